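"""Shared fixtures: small simulated clades computed once per session.

All fixture data is generated programmatically by the simulator; nothing is
read from disk. The "tiny" clade is small enough that the alignment-heavy
stages (clustering, orthologs) stay fast, while the "small" clade gives the
annotation and statistics stages realistic gene counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pytest

from pandorapan.annotate import annotate_genome
from pandorapan.cluster import all_vs_all, build_clusters, membership_table, orthologs
from pandorapan.simulate import SimParams, simulate_clade


@pytest.fixture(scope="session")
def small_clade():
    """Six-strain clade, ~45 kb genomes, annotation-scale gene counts."""
    return simulate_clade(SimParams.small(seed=101))


TINY = dict(
    ancestral_gene_count=35,
    mean_gene_codons=110.0,
    lncrna_per_genome=8.0,
    proteome_core_size=20,
    proteome_accessory_size=6,
    proteome_host_size=20,
)


@pytest.fixture(scope="session")
def tiny_clade():
    """Clade small enough for all-vs-all protein alignment in seconds."""
    return simulate_clade(SimParams.small(seed=202, **TINY))


@dataclass
class PipelineProducts:
    clade: object
    annotated: dict = field(default_factory=dict)
    proteins: dict = field(default_factory=dict)
    genome_of: dict = field(default_factory=dict)
    edges: list = field(default_factory=list)
    clusters: list = field(default_factory=list)
    membership: object = None
    ortholog_pairs: list = field(default_factory=list)
    ortholog_groups: list = field(default_factory=list)
    cds_orders: dict = field(default_factory=dict)


@pytest.fixture(scope="session")
def tiny_products(tiny_clade):
    """Annotation + clustering + orthologs computed once on the tiny clade."""
    prod = PipelineProducts(clade=tiny_clade)
    for s in sorted(tiny_clade.genomes):
        genes, _ = annotate_genome(tiny_clade.genomes[s], tiny_clade.evidence[s])
        prod.annotated[s] = genes
        for g in genes:
            if g.kind == "CDS":
                prod.proteins[g.id] = g.protein(tiny_clade.genomes[s])
                prod.genome_of[g.id] = s
        prod.cds_orders[s] = [
            g.id for g in sorted(genes, key=lambda x: x.start) if g.kind == "CDS"
        ]
    prod.edges = all_vs_all(prod.proteins)
    prod.clusters = build_clusters(prod.edges, prod.proteins, prod.genome_of)
    prod.membership = membership_table(prod.clusters, prod.genome_of)
    prod.ortholog_pairs, prod.ortholog_groups = orthologs(prod.edges, prod.genome_of)
    return prod
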
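"""Protein-family clustering from all-vs-all pairwise similarity.

A k-mer prescreen limits the quadratic pair space; surviving pairs are
aligned locally (BLOSUM62) with Biopython's PairwiseAligner. Families are
single-linkage connected components of the thresholded similarity graph,
which makes clustering invariant to input order and id renaming. Ortholog
pairs are reciprocal best hits per genome pair, grouped with at most one
gene per genome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Optional, Sequence

import networkx as nx
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

# crude Karlin-Altschul-style significance for gapped BLOSUM62 local scores
_KA_LAMBDA = 0.267
_KA_K = 0.041


@dataclass(frozen=True)
class SimilarityEdge:
    query_id: str
    subject_id: str
    identity: float          # matches / alignment columns, in [0,1]
    coverage: float          # aligned span / length of the shorter protein
    score: float
    evalue: float


@dataclass
class ProteinCluster:
    cluster_id: str
    members: tuple[str, ...]
    copy_number: dict[str, int]
    is_orfan_family: bool = True

    @property
    def n_genomes(self) -> int:
        return len(self.copy_number)


def _make_aligner(gap_open: float = -11.0, gap_extend: float = -1.0) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def kmer_prescreen(
    proteins: Mapping[str, str], k: int = 3, min_shared: int = 2
) -> list[tuple[str, str]]:
    """Candidate pairs sharing at least ``min_shared`` k-mers.

    With k=3 a pair at >=50% identity over its full length shares many exact
    3-mers with overwhelming probability, so true homolog pairs are not lost.
    """
    ids = sorted(proteins)
    kmers = {pid: _kmer_set(proteins[pid], k) for pid in ids}
    index: dict[str, list[str]] = {}
    for pid in ids:
        for km in kmers[pid]:
            index.setdefault(km, []).append(pid)
    counts: dict[tuple[str, str], int] = {}
    for km, members in index.items():
        if len(members) > 1:
            for a, b in combinations(members, 2):
                key = (a, b) if a < b else (b, a)
                counts[key] = counts.get(key, 0) + 1
    return sorted(pair for pair, n in counts.items() if n >= min_shared)


def align_pair(
    seq_a: str, seq_b: str, aligner: Optional[Align.PairwiseAligner] = None
) -> tuple[float, float, float]:
    """(identity, coverage, score) of the best local alignment."""
    aligner = aligner or _make_aligner()
    aln = aligner.align(seq_a, seq_b)[0]
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    identity = counts.identities / columns if columns else 0.0
    short = min(len(seq_a), len(seq_b))
    qspan = aln.aligned[0][-1][1] - aln.aligned[0][0][0]
    sspan = aln.aligned[1][-1][1] - aln.aligned[1][0][0]
    coverage = min(max(qspan, sspan) / short, 1.0) if short else 0.0
    return identity, coverage, float(aln.score)


def evalue_like(score: float, len_a: int, len_b: int) -> float:
    return _KA_K * len_a * len_b * math.exp(-_KA_LAMBDA * score)


def all_vs_all(
    proteins: Mapping[str, str],
    gap_open: float = -11.0,
    gap_extend: float = -1.0,
    k: int = 3,
    min_shared_kmers: int = 2,
    e_max: float = 1e-5,
) -> list[SimilarityEdge]:
    """All-vs-all local alignment of every pair passing the k-mer prescreen;
    edges above the significance ceiling are dropped. Edges are undirected
    and stored once with query_id < subject_id."""
    aligner = _make_aligner(gap_open, gap_extend)
    edges = []
    for a, b in kmer_prescreen(proteins, k=k, min_shared=min_shared_kmers):
        # score-only pass first: the full alignment is only materialized
        # for pairs that can reach the significance ceiling
        score = float(aligner.score(proteins[a], proteins[b]))
        if evalue_like(score, len(proteins[a]), len(proteins[b])) > e_max:
            continue
        identity, coverage, score = align_pair(proteins[a], proteins[b], aligner)
        ev = evalue_like(score, len(proteins[a]), len(proteins[b]))
        if ev <= e_max:
            edges.append(SimilarityEdge(a, b, identity, coverage, score, ev))
    return edges


def build_clusters(
    edges: Sequence[SimilarityEdge],
    proteins: Mapping[str, str],
    genome_of: Mapping[str, str],
    min_identity: float = 0.35,
    min_coverage: float = 0.7,
    external_homologs: Optional[set[str]] = None,
) -> list[ProteinCluster]:
    """Single-linkage connected components of the thresholded graph.

    Every protein appears in exactly one cluster (singletons allowed).
    Cluster ids are deterministic: the lexicographically smallest member.
    ``external_homologs`` (gene ids with hits outside the family, from a
    precomputed database search) switches off ORFan-family status.
    """
    g = nx.Graph()
    g.add_nodes_from(proteins)
    for e in edges:
        if e.identity >= min_identity and e.coverage >= min_coverage:
            g.add_edge(e.query_id, e.subject_id)
    external = external_homologs or set()
    clusters = []
    for comp in nx.connected_components(g):
        members = tuple(sorted(comp))
        copy_number: dict[str, int] = {}
        for m in members:
            gn = genome_of[m]
            copy_number[gn] = copy_number.get(gn, 0) + 1
        clusters.append(ProteinCluster(
            cluster_id=f"cl_{members[0]}",
            members=members,
            copy_number=copy_number,
            is_orfan_family=not any(m in external for m in members),
        ))
    clusters.sort(key=lambda c: c.cluster_id)
    return clusters


def membership_table(
    clusters: Sequence[ProteinCluster], genome_of: Mapping[str, str]
) -> pd.DataFrame:
    """Long-form (gene_id, genome_id, cluster_id) table used by the
    pan-genome, duplication, and cladistics stages."""
    rows = [
        (m, genome_of[m], c.cluster_id)
        for c in clusters
        for m in c.members
    ]
    return pd.DataFrame(rows, columns=["gene_id", "genome_id", "cluster_id"])


def orthologs(
    edges: Sequence[SimilarityEdge],
    genome_of: Mapping[str, str],
) -> tuple[list[tuple[str, str]], list[dict[str, str]]]:
    """Reciprocal-best-hit ortholog pairs per genome pair, then ortholog
    groups with at most one gene per genome.

    Best hits are ranked by score, then identity, then subject id (ties are
    broken deterministically). Groups are connected components of the RBH
    graph; components with two genes from one genome keep the gene with the
    highest summed score to the rest of the component.
    """
    best: dict[tuple[str, str], tuple[float, float, str]] = {}
    score_of: dict[tuple[str, str], float] = {}
    for e in edges:
        ga, gb = genome_of[e.query_id], genome_of[e.subject_id]
        if ga == gb:
            continue
        score_of[(e.query_id, e.subject_id)] = e.score
        score_of[(e.subject_id, e.query_id)] = e.score
        for src, dst, dst_genome in ((e.query_id, e.subject_id, gb),
                                     (e.subject_id, e.query_id, ga)):
            key = (src, dst_genome)
            cand = (e.score, e.identity, dst)
            prev = best.get(key)
            if prev is None or (cand[0], cand[1], prev[2]) > (prev[0], prev[1], cand[2]):
                best[key] = cand
    pairs = []
    for (src, dst_genome), (_, _, dst) in best.items():
        back = best.get((dst, genome_of[src]))
        if back is not None and back[2] == src and src < dst:
            pairs.append((src, dst))
    pairs.sort()

    g = nx.Graph(pairs)
    groups: list[dict[str, str]] = []
    for comp in nx.connected_components(g):
        by_genome: dict[str, list[str]] = {}
        for m in comp:
            by_genome.setdefault(genome_of[m], []).append(m)
        group = {}
        for gn, members in by_genome.items():
            if len(members) == 1:
                group[gn] = members[0]
            else:
                def total_score(m: str) -> float:
                    return sum(score_of.get((m, o), 0.0) for o in comp if o != m)
                group[gn] = max(sorted(members), key=total_score)
        groups.append(dict(sorted(group.items())))
    groups.sort(key=lambda d: min(d.values()))
    return pairs, groups
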
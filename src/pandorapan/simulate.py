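"""Forward simulator of a pandoravirus-like clade.

Generates linear GC-rich genomes for a fixed two-clade strain tree, together
with annotations, strand-specific transcript coverage, splice junctions,
peptide evidence, virion proteome tables, and a ground-truth table for every
emitted gene. The generative scenario: a shared ancestral gene repertoire
(partly in multi-copy families), tandem-biased duplications, gene losses,
de novo gene births with intergenic-like composition, rare HGT insertions,
mostly antisense lncRNAs, spliceosomal introns in a minority of genes, and
log-normal iBAQ abundances with a conserved core virion proteome.

A single NumPy Generator keyed by the seed drives every stochastic choice,
so outputs are byte-identical across runs for a fixed seed.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from . import io as pio
from .models import (
    EvidenceBundle,
    GeneModel,
    Genome,
    SENSE_CODONS,
    STOP_CODONS,
    revcomp,
    translate,
)

BASES = "ACGT"
_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)
_DECODE = {ord(b): i for i, b in enumerate(BASES)}

# K80-style mutation bookkeeping on the 0..3 encoding (A,C,G,T)
_TRANSITION = np.array([2, 3, 0, 1])
_TRANSVERSIONS = np.array([[1, 3], [0, 2], [1, 3], [0, 2]])

_ALL_CODONS = sorted(SENSE_CODONS) + sorted(STOP_CODONS)


def encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.empty(len(arr), dtype=np.uint8)
    for byte, code in _DECODE.items():
        out[arr == byte] = code
    return out


def decode(arr: np.ndarray) -> str:
    return bytes(_BASE_ARR[arr]).decode()


def _codon_gc(codon: str) -> int:
    return sum(1 for b in codon if b in "GC")


_KD = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}


def _preferred_codons() -> set[str]:
    """One deterministic preferred codon per amino acid — the simulated
    host's translationally optimal set. The middle-ranked codon of each
    synonymous family is used so that wobble positions stay heterogeneous
    (an all-GC-maximal choice would leave shifted reading frames almost
    stop-free, which inflates spurious ORF chimeras)."""
    by_aa: dict[str, list[str]] = {}
    from .models import _CODON_TABLE

    for c in SENSE_CODONS:
        by_aa.setdefault(_CODON_TABLE[c], []).append(c)
    return {sorted(codons)[len(codons) // 2] for codons in by_aa.values()}


_PREFERRED = _preferred_codons()


def coding_codon_weights(
    target_gc: float,
    hydropathy_bias: float = 0.0,
    preference_strength: float = 0.0,
) -> np.ndarray:
    """Sense-codon weights w ∝ exp(beta*GC + bias*KD(aa) + pref) with beta
    solved so the expected per-base GC fraction equals ``target_gc``.

    A positive hydropathy bias enriches order-promoting hydrophobic
    residues; ``preference_strength`` boosts one preferred codon per amino
    acid, emulating translational selection so that codon-adaptation scores
    separate selected coding sequence from random reading frames."""
    from .models import _CODON_TABLE

    gcs = np.array([_codon_gc(c) for c in SENSE_CODONS], dtype=float)
    kd = np.array([_KD[_CODON_TABLE[c]] for c in SENSE_CODONS], dtype=float)
    pref = np.array([preference_strength if c in _PREFERRED else 0.0
                     for c in SENSE_CODONS])

    def weights(beta: float) -> np.ndarray:
        w = np.exp(beta * gcs + hydropathy_bias * kd + pref)
        return w / w.sum()

    lo, hi = -25.0, 25.0
    for _ in range(80):
        mid = (lo + hi) / 2
        if float((weights(mid) * gcs).sum() / 3.0) < target_gc:
            lo = mid
        else:
            hi = mid
    return weights((lo + hi) / 2)


def base_level_codon_weights(gc: float) -> tuple[np.ndarray, float]:
    """(sense-codon weights, per-codon stop probability) for independent
    bases at the given GC fraction — the intergenic composition model."""
    p = {"A": (1 - gc) / 2, "T": (1 - gc) / 2, "G": gc / 2, "C": gc / 2}
    sense = np.array([math.prod(p[b] for b in c) for c in SENSE_CODONS])
    p_stop = sum(math.prod(p[b] for b in c) for c in STOP_CODONS)
    return sense / sense.sum(), p_stop


def random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=probs).astype(np.uint8)


def _codons_to_array(idx: np.ndarray, codons: list[str]) -> np.ndarray:
    return encode("".join(codons[i] for i in idx))


def random_cds(rng: np.random.Generator, n_codons: int, weights: np.ndarray) -> np.ndarray:
    """ATG + (n_codons-2) weighted sense codons + a stop codon."""
    idx = rng.choice(len(SENSE_CODONS), size=max(n_codons - 2, 1), p=weights)
    body = _codons_to_array(idx, SENSE_CODONS)
    stop = encode(["TAA", "TAG", "TGA"][rng.integers(3)])
    return np.concatenate([encode("ATG"), body, stop])


def mutate_sites(
    arr: np.ndarray, p: float, kappa: float, rng: np.random.Generator
) -> np.ndarray:
    """K80-like per-site substitution: each site changes with probability p;
    transitions are kappa-fold favored over each transversion."""
    out = arr.copy()
    hit = np.flatnonzero(rng.random(len(arr)) < p)
    if len(hit) == 0:
        return out
    u = rng.random(len(hit))
    is_ts = u < kappa / (kappa + 2.0)
    ts_sites = hit[is_ts]
    out[ts_sites] = _TRANSITION[arr[ts_sites]]
    tv_sites = hit[~is_ts]
    pick = rng.integers(2, size=len(tv_sites))
    out[tv_sites] = _TRANSVERSIONS[arr[tv_sites], pick]
    return out


_STOP_CODES = {tuple(encode(s)) for s in STOP_CODONS}


def _revert_new_stops(mutated: np.ndarray, original: np.ndarray) -> np.ndarray:
    """Revert any in-frame codon that a substitution turned into a stop."""
    cods = mutated.reshape(-1, 3)
    orig = original.reshape(-1, 3)
    is_stop = np.zeros(len(cods), dtype=bool)
    for s in _STOP_CODES:
        is_stop |= (cods == np.array(s, dtype=np.uint8)).all(axis=1)
    was_stop = np.zeros(len(orig), dtype=bool)
    for s in _STOP_CODES:
        was_stop |= (orig == np.array(s, dtype=np.uint8)).all(axis=1)
    bad = is_stop & ~was_stop
    cods[bad] = orig[bad]
    return cods.reshape(-1)


def evolve_cds(
    seq: str,
    branch_length: float,
    kappa: float = 2.0,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> str:
    """Codon-aware substitution along one branch.

    The expected proportion of changed sites approximates ``branch_length``
    for small values; substitutions that would create an in-frame stop codon
    are rejected (the codon is left unchanged).
    """
    if len(seq) % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    if rng is None:
        rng = np.random.default_rng(seed)
    arr = encode(seq)
    mutated = mutate_sites(arr, branch_length, kappa, rng)
    return decode(_revert_new_stops(mutated, arr))


def sample_intergenic_orf(
    gc: float,
    min_len: int,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
    coding_mixture: float = 0.0,
    coding_weights: Optional[np.ndarray] = None,
    hydropathy_bias: float = 0.0,
) -> str:
    """Sample a random ORF (ATG..stop, no internal stop) whose length
    distribution follows the chance occurrence of stop codons at the given
    base composition: higher GC makes stops rarer, hence longer ORFs.

    ``coding_mixture`` mixes in a fraction of codons drawn from a
    coding-usage distribution (used for de novo genes partway through
    selection-driven amelioration); 0 is pure intergenic composition.
    """
    if not (0.0 < gc < 1.0):
        raise ValueError("gc must be in (0,1)")
    if rng is None:
        rng = np.random.default_rng(seed)
    sense_w, p_stop = base_level_codon_weights(gc)
    if hydropathy_bias != 0.0:
        from .models import _CODON_TABLE

        kd = np.array([_KD[_CODON_TABLE[c]] for c in SENSE_CODONS])
        sense_w = sense_w * np.exp(hydropathy_bias * kd)
        sense_w /= sense_w.sum()
    min_interior = max(int(math.ceil(min_len / 3.0)) - 2, 1)
    n_interior = min_interior + int(rng.geometric(p_stop)) - 1
    idx = rng.choice(len(SENSE_CODONS), size=n_interior, p=sense_w)
    if coding_mixture > 0.0 and coding_weights is not None:
        take = rng.random(n_interior) < coding_mixture
        idx[take] = rng.choice(
            len(SENSE_CODONS), size=int(take.sum()), p=coding_weights
        )
    body = "".join(SENSE_CODONS[i] for i in idx)
    stops = sorted(STOP_CODONS)
    # choose the stop codon by its base-level probability
    pstops = np.array(
        [math.prod({"A": (1 - gc) / 2, "T": (1 - gc) / 2,
                    "G": gc / 2, "C": gc / 2}[b] for b in s) for s in stops]
    )
    stop = stops[rng.choice(3, p=pstops / pstops.sum())]
    return "ATG" + body + stop


# ------------------------------------------------------------------ params


@dataclass
class SimParams:
    """Study conditions of the simulated clade.

    Rates are events per gene per branch; branch lengths are expected
    substitutions per site. Defaults emulate the observed family regime:
    ~2 Mb linear genomes at ~60% GC with ~35% intergenic sequence, about
    half of the genes in multi-copy families, tandem-biased duplications,
    and short intergenic-like de novo genes.
    """

    n_strains: int = 6
    seed: int = 0
    ancestral_gene_count: int = 950
    mean_gene_codons: float = 360.0
    gene_len_sigma: float = 0.5
    mean_spacer_len: float = 560.0
    spacer_len_sigma: float = 0.6
    genome_gc_coding: float = 0.66
    genome_gc_intergenic: float = 0.57
    genome_gc_denovo: float = 0.57
    genome_gc_hgt: float = 0.45
    intergenic_fraction: float = 0.35
    stem_branch_length: float = 0.10
    tip_branch_length: float = 0.05
    kappa: float = 2.0
    dup_rate: float = 0.04
    loss_rate: float = 0.02
    birth_rate: float = 0.03
    hgt_rate: float = 0.005
    tandem_geom_p: float = 0.6
    denovo_min_len: int = 300
    denovo_min_len_stem: int = 360
    denovo_coding_mixture: float = 0.28
    denovo_coding_mixture_stem: float = 0.5
    coding_hydropathy_bias: float = 0.1
    denovo_hydropathy_bias: float = -0.15
    codon_preference_strength: float = 1.0
    omega_ancestral: float = 0.4
    omega_denovo: float = 0.9
    omega_hgt: float = 0.6
    clade_omega_factor: Optional[dict[str, float]] = None
    birth_zone: tuple[float, float] = (0.0, 1.0)
    paralog_drift_scale: float = 25.0
    utr_length_mean: float = 150.0
    intron_rate: float = 0.10
    lncrna_per_genome: float = 200.0
    expressed_fraction: float = 0.97
    peptide_fraction: float = 0.7
    proteome_core_size: int = 150
    proteome_accessory_size: int = 60
    proteome_host_size: int = 150
    ibaq_mu: float = 5.5
    ibaq_sigma: float = 1.2
    ibaq_strain_sigma: float = 0.5
    ibaq_replicate_sigma: float = 0.1
    n_replicates: int = 3
    plant_intergenic_matches: int = 2
    max_growth_factor: float = 10.0

    def __post_init__(self) -> None:
        for name in ("dup_rate", "loss_rate", "birth_rate", "hgt_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("genome_gc_coding", "genome_gc_intergenic", "intergenic_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1]")
        if self.n_strains < 2:
            raise ValueError("need at least 2 strains")

    @classmethod
    def small(cls, seed: int = 0, **over) -> "SimParams":
        """A desk-scale clade (same structure, ~40 kb genomes) used for
        fast tests and demonstrations."""
        defaults = dict(
            seed=seed,
            ancestral_gene_count=60,
            mean_gene_codons=160.0,
            mean_spacer_len=200.0,
            lncrna_per_genome=12.0,
            proteome_core_size=40,
            proteome_accessory_size=12,
            proteome_host_size=40,
            plant_intergenic_matches=1,
        )
        defaults.update(over)
        return cls(**defaults)


@dataclass
class SimGene:
    uid: int
    family: str
    origin: str                 # ancestral | duplication | de_novo | hgt
    birth_branch: str
    strand: str
    cds: np.ndarray             # coding orientation, ATG..stop, uint8 codes
    parent_family: Optional[str] = None
    omega: float = 1.0          # purifying-selection strength (dN/dS target)


@dataclass
class GenomeState:
    genes: list[SimGene]
    spacers: list[np.ndarray]   # len(genes) + 1

    def total_length(self) -> int:
        return sum(len(g.cds) for g in self.genes) + sum(len(s) for s in self.spacers)


@dataclass
class TruthTable:
    """Ground truth: per-gene origin/family records plus true lncRNAs and
    planted intergenic homologs."""

    genes: pd.DataFrame
    lncrnas: pd.DataFrame
    planted: pd.DataFrame

    def categories(self, clade_map: dict[str, str]) -> pd.DataFrame:
        """True core/clade_specific/strain_specific label per family, from
        the strain presence pattern of each family."""
        strains = sorted(clade_map)
        clades: dict[str, set[str]] = {}
        for s, c in clade_map.items():
            clades.setdefault(c, set()).add(s)
        pres = self.genes.groupby("family")["genome_id"].agg(set)
        rows = []
        for fam, present in pres.items():
            if present == set(strains):
                cat = "core"
            elif len(present) == 1:
                cat = "strain_specific"
            elif any(present == members and len(members) >= 2
                     for members in clades.values()):
                cat = "clade_specific"
            else:
                cat = "accessory"
            rows.append((fam, cat))
        return pd.DataFrame(rows, columns=["family", "category"])


@dataclass
class SimulatedClade:
    params: SimParams
    genomes: dict[str, Genome]
    genes: dict[str, list[GeneModel]]
    evidence: dict[str, EvidenceBundle]
    proteome: pd.DataFrame
    truth: TruthTable
    clade_map: dict[str, str]
    tree_newick: str
    reference_usage: dict[str, int]

    def proteins(self, strain: str) -> dict[str, str]:
        g = self.genomes[strain]
        return {
            gene.id: gene.protein(g)
            for gene in self.genes[strain]
            if gene.kind == "CDS"
        }

    def all_proteins(self) -> tuple[dict[str, str], dict[str, str]]:
        """(protein sequences, gene->genome map) over all strains."""
        seqs: dict[str, str] = {}
        genome_of: dict[str, str] = {}
        for strain in sorted(self.genomes):
            for pid, seq in self.proteins(strain).items():
                seqs[pid] = seq
                genome_of[pid] = strain
        return seqs, genome_of

    def write(self, outdir: str) -> None:
        os.makedirs(outdir, exist_ok=True)
        pio.write_fasta(
            [self.genomes[s] for s in sorted(self.genomes)],
            os.path.join(outdir, "genomes.fasta"),
        )
        all_genes = [g for s in sorted(self.genes) for g in self.genes[s]]
        pio.write_gff3(all_genes, os.path.join(outdir, "genes.gff3"))
        for strain in sorted(self.evidence):
            ev = self.evidence[strain]
            pio.write_bedgraph(
                ev.coverage_plus, strain, os.path.join(outdir, f"{strain}.plus.bedgraph")
            )
            pio.write_bedgraph(
                ev.coverage_minus, strain, os.path.join(outdir, f"{strain}.minus.bedgraph")
            )
            pio.write_junctions(ev.junctions, os.path.join(outdir, f"{strain}.junctions.tsv"))
            pio.write_peptides(ev.peptides, os.path.join(outdir, f"{strain}.peptides.tsv"))
        pio.write_table(self.proteome, os.path.join(outdir, "proteome.tsv"))
        pio.write_table(self.truth.genes, os.path.join(outdir, "truth_genes.tsv"))
        pio.write_table(self.truth.lncrnas, os.path.join(outdir, "truth_lncrnas.tsv"))
        pio.write_table(self.truth.planted, os.path.join(outdir, "truth_planted.tsv"))
        usage = pd.DataFrame(
            sorted(self.reference_usage.items()), columns=["codon", "count"]
        )
        pio.write_table(usage, os.path.join(outdir, "reference_codon_usage.tsv"))
        with open(os.path.join(outdir, "tree.nwk"), "w") as fh:
            fh.write(self.tree_newick + "\n")
        pd.DataFrame(
            sorted(self.clade_map.items()), columns=["genome_id", "clade"]
        ).to_csv(os.path.join(outdir, "clades.tsv"), sep="\t", index=False)


# ------------------------------------------------------------------ simulator


class _Sim:
    def __init__(self, params: SimParams):
        self.p = params
        self.rng = np.random.default_rng(params.seed)
        self.uid = 0
        self.fam_counter = 0
        self.coding_w = coding_codon_weights(
            params.genome_gc_coding, params.coding_hydropathy_bias,
            params.codon_preference_strength,
        )

    def next_uid(self) -> int:
        self.uid += 1
        return self.uid

    def new_family(self, prefix: str) -> str:
        self.fam_counter += 1
        return f"{prefix}{self.fam_counter:05d}"

    # -- ancestral genome ------------------------------------------------

    def _family_size(self) -> int:
        u = self.rng.random()
        if u < 0.80:
            return 1
        if u < 0.92:
            return 2
        if u < 0.96:
            return 3
        if u < 0.99:
            return int(self.rng.integers(4, 9))
        return int(self.rng.integers(10, 31))

    def _gene_length_codons(self) -> int:
        n = int(self.rng.lognormal(math.log(self.p.mean_gene_codons),
                                   self.p.gene_len_sigma))
        return int(np.clip(n, 100, 2000))

    def _spacer(self) -> np.ndarray:
        n = int(self.rng.lognormal(math.log(self.p.mean_spacer_len),
                                   self.p.spacer_len_sigma))
        n = max(n, 50)
        return random_bases(self.rng, n, self.p.genome_gc_intergenic)

    def ancestral_genome(self) -> GenomeState:
        """Ancestral repertoire: partly multi-copy families; younger
        paralogs (less diverged) sit next to their siblings, older ones
        have drifted apart — the tandem-duplication age signal."""
        genes: list[SimGene] = []
        drifted: list[tuple[SimGene, float]] = []
        remaining = self.p.ancestral_gene_count
        while remaining > 0:
            size = min(self._family_size(), remaining)
            fam = self.new_family("FA")
            base = random_cds(self.rng, self._gene_length_codons(), self.coding_w)
            strand = "+" if self.rng.random() < 0.5 else "-"
            for k in range(size):
                gene = SimGene(self.next_uid(), fam, "ancestral", "root",
                               strand, base.copy(), omega=self.p.omega_ancestral)
                if k == 0:
                    genes.append(gene)
                else:
                    bl = float(self.rng.uniform(0.02, 0.20))
                    gene.cds = self._mutate_gene(base.copy(), bl, gene.omega)
                    drifted.append((gene, bl))
            remaining -= size
        for gene, bl in drifted:
            # rank offset from the family founder grows with divergence
            fam_pos = max(i for i, g in enumerate(genes) if g.family == gene.family)
            shift = 1 + int(self.rng.poisson(self.p.paralog_drift_scale * bl))
            pos = min(fam_pos + shift, len(genes))
            genes.insert(pos, gene)
        spacers = [self._spacer() for _ in range(len(genes) + 1)]
        return GenomeState(genes, spacers)

    # -- branch evolution ------------------------------------------------

    def _mutate_gene(self, cds: np.ndarray, bl: float, omega: float = 1.0) -> np.ndarray:
        """Substitute along a branch; new stops are rejected, and amino-acid
        changing codons are reverted with probability 1 - omega (purifying
        selection of the requested strength)."""
        mutated = mutate_sites(cds, bl, self.p.kappa, self.rng)
        mutated = _revert_new_stops(mutated, cds)
        if omega < 1.0:
            old_aa = translate(decode(cds), trim_stop=False)
            new_aa = translate(decode(mutated), trim_stop=False)
            for i, (a, b) in enumerate(zip(old_aa, new_aa)):
                if a != b and self.rng.random() > omega:
                    mutated[3 * i:3 * i + 3] = cds[3 * i:3 * i + 3]
            mutated = _revert_new_stops(mutated, cds)
        mutated[:3] = cds[:3]       # preserve the start codon
        mutated[-3:] = cds[-3:]     # preserve the stop codon
        return mutated

    def _branch_omega(self, gene: SimGene, branch: str) -> float:
        factor = 1.0
        if self.p.clade_omega_factor:
            clade = branch.split("_", 1)[1][0]
            factor = self.p.clade_omega_factor.get(clade, 1.0)
        return min(gene.omega * factor, 1.0)

    def evolve_branch(self, state: GenomeState, bl: float, branch: str) -> GenomeState:
        p = self.p
        genes = [
            replace(g, cds=self._mutate_gene(g.cds, bl, self._branch_omega(g, branch)))
            for g in state.genes
        ]
        spacers = [
            mutate_sites(s, bl, p.kappa, self.rng) for s in state.spacers
        ]
        # losses (merge flanking spacers)
        keep = self.rng.random(len(genes)) >= p.loss_rate
        new_genes: list[SimGene] = []
        new_spacers: list[np.ndarray] = [spacers[0]]
        for i, g in enumerate(genes):
            if keep[i]:
                new_genes.append(g)
                new_spacers.append(spacers[i + 1])
            else:
                new_spacers[-1] = np.concatenate([new_spacers[-1], spacers[i + 1]])
        genes, spacers = new_genes, new_spacers
        # tandem-biased duplications
        dup_idx = np.flatnonzero(self.rng.random(len(genes)) < p.dup_rate)
        for i in sorted(dup_idx, reverse=True):
            src = genes[i]
            copy_cds = self._mutate_gene(src.cds, 0.01, src.omega)
            copy = SimGene(self.next_uid(), src.family, "duplication", branch,
                           src.strand, copy_cds, parent_family=src.family,
                           omega=src.omega)
            offset = int(self.rng.geometric(p.tandem_geom_p))
            pos = min(i + offset, len(genes))
            genes.insert(pos, copy)
            spacers.insert(pos + 1, self._spacer())
        # de novo births from intergenic-like composition
        def _birth_pos() -> int:
            lo = int(p.birth_zone[0] * (len(genes) + 1))
            hi = max(int(p.birth_zone[1] * (len(genes) + 1)), lo + 1)
            return int(self.rng.integers(lo, hi))

        n_birth = int(self.rng.binomial(max(len(genes), 1), p.birth_rate))
        is_stem = branch.startswith("stem")
        for _ in range(n_birth):
            # stem-born genes are older at observation time: longer and
            # further ameliorated toward coding composition than tip-born
            orf = sample_intergenic_orf(
                p.genome_gc_denovo,
                p.denovo_min_len_stem if is_stem else p.denovo_min_len,
                rng=self.rng,
                coding_mixture=(p.denovo_coding_mixture_stem if is_stem
                                else p.denovo_coding_mixture),
                coding_weights=self.coding_w,
                hydropathy_bias=p.denovo_hydropathy_bias,
            )
            fam = self.new_family("FD")
            strand = "+" if self.rng.random() < 0.5 else "-"
            pos = _birth_pos()
            genes.insert(pos, SimGene(self.next_uid(), fam, "de_novo", branch,
                                      strand, encode(orf), omega=p.omega_denovo))
            spacers.insert(pos + 1, self._spacer())
        # HGT insertions with foreign composition
        n_hgt = int(self.rng.binomial(max(len(genes), 1), p.hgt_rate))
        for _ in range(n_hgt):
            w = coding_codon_weights(p.genome_gc_hgt, p.coding_hydropathy_bias,
                                     p.codon_preference_strength)
            cds = random_cds(self.rng, self._gene_length_codons(), w)
            fam = self.new_family("FH")
            strand = "+" if self.rng.random() < 0.5 else "-"
            pos = _birth_pos()
            genes.insert(pos, SimGene(self.next_uid(), fam, "hgt", branch,
                                      strand, cds, parent_family="donor",
                                      omega=p.omega_hgt))
            spacers.insert(pos + 1, self._spacer())
        return GenomeState(genes, spacers)


def _strain_names(n: int) -> tuple[list[str], dict[str, str]]:
    n_a = (n + 1) // 2
    names = [f"A{i+1}" for i in range(n_a)] + [f"B{i+1}" for i in range(n - n_a)]
    clade_map = {s: s[0] for s in names}
    return names, clade_map


def _tree_newick(names: list[str], clade_map: dict[str, str],
                 tip_bl: float, stem_bl: float) -> str:
    clades: dict[str, list[str]] = {}
    for s in names:
        clades.setdefault(clade_map[s], []).append(s)
    parts = []
    for c in sorted(clades):
        tips = ",".join(f"{t}:{tip_bl}" for t in clades[c])
        parts.append(f"({tips}){c}:{stem_bl}")
    return "(" + ",".join(parts) + ")root;"


def simulate_clade(params: SimParams) -> SimulatedClade:
    """Run the forward simulation and assemble all outputs.

    Raises RuntimeError if the event rates inflate any genome beyond
    ``max_growth_factor`` times the ancestral length.
    """
    sim = _Sim(params)
    p = params
    names, clade_map = _strain_names(p.n_strains)
    ancestor = sim.ancestral_genome()
    anc_len = ancestor.total_length()

    # evolve down the fixed two-clade topology
    clade_states: dict[str, GenomeState] = {}
    for clade in sorted(set(clade_map.values())):
        clade_states[clade] = sim.evolve_branch(
            ancestor, p.stem_branch_length, f"stem_{clade}"
        )
    leaf_states: dict[str, GenomeState] = {}
    for s in names:
        leaf_states[s] = sim.evolve_branch(
            clade_states[clade_map[s]], p.tip_branch_length, f"tip_{s}"
        )
        if leaf_states[s].total_length() > p.max_growth_factor * anc_len:
            raise RuntimeError(
                f"genome growth exceeded {p.max_growth_factor}x the ancestral "
                f"length in strain {s}; lower dup/birth/hgt rates"
            )

    planted_rows = _plant_intergenic_matches(sim, leaf_states, names, clade_map)

    genomes: dict[str, Genome] = {}
    gene_models: dict[str, list[GeneModel]] = {}
    evidence: dict[str, EvidenceBundle] = {}
    truth_gene_rows: list[dict] = []
    truth_lnc_rows: list[dict] = []
    for s in names:
        genome, models, ev, g_rows, l_rows = _assemble_leaf(sim, s, leaf_states[s])
        genomes[s] = genome
        gene_models[s] = models
        evidence[s] = ev
        truth_gene_rows.extend(g_rows)
        truth_lnc_rows.extend(l_rows)

    truth = TruthTable(
        genes=pd.DataFrame(truth_gene_rows),
        lncrnas=pd.DataFrame(
            truth_lnc_rows, columns=["genome_id", "start", "end", "strand", "context"]
        ),
        planted=pd.DataFrame(
            planted_rows,
            columns=["query_gene", "query_genome", "subject_genome",
                     "anchor_family", "subject_start_hint"],
        ),
    )
    proteome = _simulate_proteome(sim, truth, gene_models, names)
    usage_counts = {
        c: int(round(w * 100000))
        for c, w in zip(SENSE_CODONS, sim.coding_w)
    }
    return SimulatedClade(
        params=params,
        genomes=genomes,
        genes=gene_models,
        evidence=evidence,
        proteome=proteome,
        truth=truth,
        clade_map=clade_map,
        tree_newick=_tree_newick(names, clade_map, p.tip_branch_length,
                                 p.stem_branch_length),
        reference_usage=usage_counts,
    )


def _plant_intergenic_matches(
    sim: _Sim,
    leaf_states: dict[str, GenomeState],
    names: list[str],
    clade_map: dict[str, str],
) -> list[tuple]:
    """Copy a degraded (non-coding) version of a few de novo genes into the
    homologous spacer of a sister strain — the signature the intergenic
    homology scan is designed to recover."""
    p = sim.p
    rows: list[tuple] = []
    if p.plant_intergenic_matches <= 0:
        return rows
    for query_strain in names:
        if len(rows) >= p.plant_intergenic_matches:
            break
        sisters = [t for t in names
                   if t != query_strain and clade_map[t] == clade_map[query_strain]]
        if not sisters:
            continue
        subject_strain = sisters[0]
        q_state = leaf_states[query_strain]
        s_state = leaf_states[subject_strain]
        s_fam_pos = {}
        for j, g in enumerate(s_state.genes):
            s_fam_pos.setdefault(g.family, j)
        for i, g in enumerate(q_state.genes):
            if g.origin != "de_novo" or len(g.cds) < p.denovo_min_len:
                continue
            # anchor on the nearest upstream shared-family neighbour
            anchor = None
            for k in range(i - 1, -1, -1):
                if q_state.genes[k].family in s_fam_pos:
                    anchor = q_state.genes[k].family
                    break
            if anchor is None:
                continue
            degraded = mutate_sites(g.cds.copy(), 0.08, p.kappa, sim.rng)
            degraded[:3] = encode("ATA")  # knock out the start
            for frac in (0.35, 0.65):     # insert premature stops
                cpos = 3 * int(len(degraded) // 3 * frac)
                degraded[cpos:cpos + 3] = encode("TAA")
            j = s_fam_pos[anchor]
            s_state.spacers[j + 1] = np.concatenate(
                [s_state.spacers[j + 1], degraded, random_bases(sim.rng, 40,
                 p.genome_gc_intergenic)]
            )
            rows.append((f"{query_strain}_g{g.uid:05d}", query_strain,
                         subject_strain, anchor, -1))
            break
    return rows


def _assemble_leaf(sim: _Sim, strain: str, state: GenomeState):
    p = sim.p
    rng = sim.rng
    parts: list[str] = []
    pos = 0
    models: list[GeneModel] = []
    truth_rows: list[dict] = []
    spacer_spans: list[tuple[int, int]] = []

    for i, gene in enumerate(state.genes):
        sp = decode(state.spacers[i])
        spacer_spans.append((pos, pos + len(sp)))
        parts.append(sp)
        pos += len(sp)
        cds = decode(gene.cds)
        exons: list[tuple[int, int]]
        has_intron = rng.random() < p.intron_rate and len(cds) >= 120
        if has_intron:
            intron = _stopless_intron(rng, p.genome_gc_intergenic)
            k = 3 * int(rng.integers(10, len(cds) // 3 - 5))
            coding_seq = cds[:k] + intron + cds[k:]
            if gene.strand == "+":
                exons = [(pos, pos + k), (pos + k + len(intron), pos + len(coding_seq))]
            else:
                coding_seq = revcomp(coding_seq)
                right = len(coding_seq)
                exons = [(pos, pos + right - k - len(intron)),
                         (pos + right - k, pos + right)]
            genomic = coding_seq
        else:
            genomic = cds if gene.strand == "+" else revcomp(cds)
            exons = [(pos, pos + len(genomic))]
        gid = f"{strain}_g{gene.uid:05d}"
        start, end = pos, pos + len(genomic)
        models.append(GeneModel(
            id=gid, genome_id=strain, start=start, end=end, strand=gene.strand,
            kind="CDS", exons=exons,
            attributes={"family": gene.family},
        ))
        truth_rows.append(dict(
            gene_id=gid, genome_id=strain, family=gene.family,
            origin=gene.origin, birth_branch=gene.birth_branch,
            strand=gene.strand, start=start, end=end, omega=gene.omega,
            has_intron=bool(has_intron), expressed=False, has_peptide=False,
        ))
        parts.append(genomic)
        pos = end
    sp = decode(state.spacers[-1])
    spacer_spans.append((pos, pos + len(sp)))
    parts.append(sp)
    sequence = "".join(parts)
    genome = Genome(id=strain, sequence=sequence)

    glen = len(sequence)
    cov_plus = np.zeros(glen)
    cov_minus = np.zeros(glen)
    junctions: list[tuple[int, int, str, int]] = []
    peptides: list[tuple[str, str, int]] = []

    for i, (model, row) in enumerate(zip(models, truth_rows)):
        expressed = rng.random() < p.expressed_fraction
        row["expressed"] = expressed
        # UTRs stay within a third of the flanking spacer so neighbouring
        # transcription units remain separable
        left_room = (spacer_spans[i][1] - spacer_spans[i][0]) // 3
        right_room = (spacer_spans[i + 1][1] - spacer_spans[i + 1][0]) // 3
        utr_left = min(int(rng.exponential(p.utr_length_mean)) + 20, left_room)
        utr_right = min(int(rng.exponential(p.utr_length_mean)) + 20, right_room)
        utr5, utr3 = (utr_left, utr_right) if model.strand == "+" else (utr_right, utr_left)
        if not expressed:
            continue
        depth = 6.0 + float(rng.lognormal(2.5, 1.0))
        lo = max(model.start - (utr5 if model.strand == "+" else utr3), 0)
        hi = min(model.end + (utr3 if model.strand == "+" else utr5), glen)
        cov = cov_plus if model.strand == "+" else cov_minus
        cov[lo:hi] += depth
        if model.n_introns:
            for (e1s, e1e), (e2s, _) in zip(model.exons, model.exons[1:]):
                junctions.append(
                    (e1e, e2s, model.strand, int(rng.integers(4, 40)))
                )
        if rng.random() < p.peptide_fraction:
            prot = model.protein(genome)
            frags = _tryptic_fragments(prot)
            if frags:
                take = rng.choice(len(frags), size=min(3, len(frags)), replace=False)
                for t in sorted(take):
                    peptides.append(
                        (model.id, frags[t], int(rng.integers(1, 20)))
                    )
                row["has_peptide"] = True

    lnc_rows: list[dict] = []
    n_lnc = int(rng.poisson(p.lncrna_per_genome))
    cds_models = [m for m in models]
    for _ in range(n_lnc):
        if cds_models and rng.random() < 0.7:
            tgt = cds_models[int(rng.integers(len(cds_models)))]
            span = tgt.end - tgt.start
            length = int(rng.integers(200, min(max(span, 201), 450) + 1))
            start = tgt.start + int(rng.integers(0, max(span - length, 0) + 1))
            strand = "-" if tgt.strand == "+" else "+"
            context = "antisense"
        else:
            big = [sp for sp in spacer_spans if sp[1] - sp[0] >= 620]
            if not big:
                continue
            s0, e0 = big[int(rng.integers(len(big)))]
            # middle third of the spacer: clear of flanking gene UTRs
            margin = (e0 - s0) // 3
            room = e0 - s0 - 2 * margin
            length = int(rng.integers(200, min(room, 800) + 1))
            start = s0 + margin + int(rng.integers(0, room - length + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            context = "intergenic"
        end = start + length
        depth = 6.0 + float(rng.lognormal(2.0, 0.8))
        cov = cov_plus if strand == "+" else cov_minus
        cov[start:end] += depth
        lnc_rows.append(dict(genome_id=strain, start=start, end=end,
                             strand=strand, context=context))

    ev = EvidenceBundle(
        genome_id=strain, coverage_plus=cov_plus, coverage_minus=cov_minus,
        junctions=junctions, peptides=peptides,
    )
    return genome, models, ev, truth_rows, lnc_rows


def _stopless_intron(rng: np.random.Generator, gc: float) -> str:
    """GT..AG intron, length divisible by 3 and free of in-frame stops, so
    the unspliced gene still reads through as one ORF and the intron is
    detectable purely from junction evidence."""
    sense_w, _ = base_level_codon_weights(gc)
    n_codons = int(rng.integers(20, 66))
    idx = rng.choice(len(SENSE_CODONS), size=n_codons, p=sense_w)
    codons = [SENSE_CODONS[i] for i in idx]
    codons[0] = "GT" + codons[0][2]
    last = codons[-1]
    tail = last[0] + "AG"
    if tail in STOP_CODONS:  # TAG: swap the first base
        tail = "CAG"
    codons[-1] = tail
    return "".join(codons)


def _tryptic_fragments(protein: str, min_len: int = 7) -> list[str]:
    frags, cur = [], []
    for aa in protein:
        cur.append(aa)
        if aa in "KR":
            frag = "".join(cur)
            if len(frag) >= min_len:
                frags.append(frag)
            cur = []
    frag = "".join(cur)
    if len(frag) >= min_len:
        frags.append(frag)
    return frags


def _simulate_proteome(
    sim: _Sim,
    truth: TruthTable,
    gene_models: dict[str, list[GeneModel]],
    names: list[str],
) -> pd.DataFrame:
    """Virion proteome tables: a conserved core of abundant viral proteins
    with correlated log-abundances across strains, a strain-specific viral
    accessory tail, and host contaminants concentrated at low ranks."""
    p = sim.p
    rng = sim.rng
    genes = truth.genes
    fam_strains = genes.groupby("family")["genome_id"].agg(set)
    shared = sorted(f for f, ss in fam_strains.items() if ss == set(names))
    rng.shuffle(shared)
    core_fams = shared[:p.proteome_core_size]
    base_ab = {
        f: rng.normal(p.ibaq_mu, p.ibaq_sigma) for f in core_fams
    }
    fam_gene = {
        (r.genome_id, r.family): r.gene_id
        for r in genes.sort_values("gene_id").itertuples()
    }
    host_pool = [f"host_p{i:04d}" for i in range(2 * p.proteome_host_size)]
    rows = []
    for strain in names:
        for fam in core_fams:
            gid = fam_gene.get((strain, fam))
            if gid is None:
                continue
            log_ab = base_ab[fam] + rng.normal(0, p.ibaq_strain_sigma)
            rows.append((strain, gid, "viral", fam, log_ab))
        strain_fams = sorted(
            set(genes.loc[genes.genome_id == strain, "family"]) - set(core_fams)
        )
        rng.shuffle(strain_fams)
        for fam in strain_fams[:p.proteome_accessory_size]:
            gid = fam_gene[(strain, fam)]
            rows.append((strain, gid, "viral", fam,
                         rng.normal(p.ibaq_mu - 1.3, 0.8)))
        take = rng.choice(len(host_pool), size=p.proteome_host_size, replace=False)
        for t in sorted(take):
            rows.append((strain, host_pool[t], "host", "",
                         rng.normal(p.ibaq_mu - 2.1, 0.7)))
    df = pd.DataFrame(rows, columns=["strain", "protein_id", "source",
                                     "family", "log_abundance"])
    for r in range(1, p.n_replicates + 1):
        noise = rng.normal(0, p.ibaq_replicate_sigma, size=len(df))
        df[f"ibaq_r{r}"] = np.power(10.0, df["log_abundance"].to_numpy() + noise)
    return df.drop(columns=["log_abundance"])
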
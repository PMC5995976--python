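"""Gene duplication statistics and pairwise dN/dS.

dN/dS uses the Nei-Gojobori (1986) counting method: synonymous and
nonsynonymous site counts per codon are obtained by enumerating the three
possible single-nucleotide changes at each position (changes to stop codons
count as nonsynonymous, so N + S = 3 per codon); observed differences
between codons with multiple substitutions are averaged over the shortest
mutational pathways, excluding pathways through stop codons; proportions
are Jukes-Cantor corrected, d = -3/4 ln(1 - 4p/3). Results are labelled
"NG86 pairwise" — they are counting estimates, not ML codon-model fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import STOP_CODONS, _CODON_TABLE

_BASES = "ACGT"


def _syn_fraction(codon: str, pos: int) -> float:
    """Fraction of the 3 single-nucleotide changes at ``pos`` that are
    synonymous. Changes producing a stop codon are nonsynonymous."""
    aa = _CODON_TABLE[codon]
    syn = 0
    for b in _BASES:
        if b == codon[pos]:
            continue
        alt = codon[:pos] + b + codon[pos + 1:]
        if _CODON_TABLE[alt] == aa and alt not in STOP_CODONS:
            syn += 1
    return syn / 3.0


# per-codon synonymous site counts, precomputed for all 61 sense codons
SYN_SITES: dict[str, float] = {
    codon: sum(_syn_fraction(codon, p) for p in range(3))
    for codon in _CODON_TABLE
    if codon not in STOP_CODONS
}


def _pathway_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(nonsynonymous, synonymous) differences between two codons, averaged
    over all shortest mutational pathways that avoid stop codons. If every
    pathway passes through a stop, all pathways are used."""
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order: tuple[int, ...], allow_stops: bool) -> Optional[tuple[float, float]]:
        nd = sd = 0.0
        cur = codon_a
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS and not allow_stops and nxt != codon_b:
                return None
            if _CODON_TABLE[cur] == _CODON_TABLE[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        return nd, sd

    results = [r for order in permutations(diff_pos)
               if (r := walk(order, allow_stops=False)) is not None]
    if not results:
        results = [walk(order, allow_stops=True) for order in permutations(diff_pos)]
    nd = float(np.mean([r[0] for r in results]))
    sd = float(np.mean([r[1] for r in results]))
    return nd, sd


@dataclass
class DnDsResult:
    n_sites: float
    s_sites: float
    nd: float
    sd: float
    pn: float
    ps: float
    dn: float
    ds: float
    omega: Optional[float]   # None when dS = 0 (undefined)


def _jc_correct(p: float) -> float:
    if p >= 0.75:
        return float("inf")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86(seq_a: str, seq_b: str) -> DnDsResult:
    """Pairwise NG86 dN/dS on an equal-length, gap-free, in-frame pair."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences differ in length")
    if len(seq_a) % 3 != 0 or len(seq_a) == 0:
        raise ValueError("length must be a positive multiple of 3")
    n_sites = s_sites = 0.0
    nd = sd = 0.0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i:i + 3], seq_b[i:i + 3]
        if ca in STOP_CODONS or cb in STOP_CODONS:
            if i == len(seq_a) - 3 and ca in STOP_CODONS and cb in STOP_CODONS:
                continue  # aligned terminal stops are ignored
            raise ValueError(f"internal stop codon at codon {i // 3}")
        sa, sb = SYN_SITES[ca], SYN_SITES[cb]
        s_sites += (sa + sb) / 2.0
        n_sites += 3.0 - (sa + sb) / 2.0
        d_nd, d_sd = _pathway_counts(ca, cb)
        nd += d_nd
        sd += d_sd
    pn = nd / n_sites if n_sites > 0 else 0.0
    ps = sd / s_sites if s_sites > 0 else 0.0
    dn, ds = _jc_correct(pn), _jc_correct(ps)
    omega = dn / ds if ds > 0 else None
    return DnDsResult(n_sites, s_sites, nd, sd, pn, ps, dn, ds, omega)


# ----------------------------------------------------- duplication stats


def copy_number_stats(membership: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-genome single/multi-copy proportions and the within-genome
    family-size histogram.

    A gene is multi-copy when its cluster holds >= 2 genes from the same
    genome.
    """
    sizes = membership.groupby(["genome_id", "cluster_id"])["gene_id"].count()
    rows = []
    for genome, sub in sizes.groupby(level=0):
        total = int(sub.sum())
        multi = int(sub[sub >= 2].sum())
        rows.append((genome, total, multi / total if total else 0.0))
    per_genome = pd.DataFrame(rows, columns=["genome_id", "n_genes",
                                             "multi_copy_fraction"])
    hist = (
        sizes.rename("family_size").reset_index()
        .groupby(["genome_id", "family_size"]).size()
        .rename("n_families").reset_index()
    )
    return per_genome, hist


def closest_paralog_distances(
    orders: Mapping[str, Sequence[str]],
    membership: pd.DataFrame,
) -> pd.DataFrame:
    """For every multi-copy family in every genome, the minimum gene-rank
    distance among member pairs (1 = adjacent genes)."""
    rows = []
    for genome, sub in membership.groupby("genome_id"):
        rank = {g: i for i, g in enumerate(orders[genome])}
        for cluster_id, fam in sub.groupby("cluster_id"):
            members = [g for g in fam["gene_id"] if g in rank]
            if len(members) < 2:
                continue
            positions = sorted(rank[g] for g in members)
            dmin = min(b - a for a, b in zip(positions, positions[1:]))
            rows.append((genome, cluster_id, len(members), dmin))
    return pd.DataFrame(rows, columns=["genome_id", "cluster_id",
                                       "n_copies", "min_rank_distance"])


def distance_divergence_correlation(
    pairs: pd.DataFrame,
    n_perm: int = 999,
    seed: Optional[int] = None,
) -> tuple[float, float]:
    """Spearman correlation between paralog protein divergence (a proxy for
    duplication age) and gene-rank distance, with a permutation p-value
    (one-sided, positive association)."""
    if len(pairs) < 10:
        raise ValueError("need at least 10 paralog pairs")
    x = pairs["min_rank_distance"].to_numpy(dtype=float)
    y = pairs["divergence"].to_numpy(dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        return 0.0, 1.0  # constant input: correlation undefined, null kept
    rho = stats.spearmanr(x, y).statistic
    if np.isnan(rho):
        return 0.0, 1.0
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = stats.spearmanr(x, rng.permutation(y)).statistic
    null = np.nan_to_num(null)
    p = (1 + np.sum(null >= rho)) / (n_perm + 1)
    return float(rho), float(p)


def protein_p_distance(prot_a: str, prot_b: str) -> float:
    """Proportion of differing residues over ungapped aligned length
    (sequences must be pre-aligned or equal length)."""
    n = min(len(prot_a), len(prot_b))
    if n == 0:
        return float("nan")
    diff = sum(1 for a, b in zip(prot_a[:n], prot_b[:n]) if a != b)
    return diff / n


# ------------------------------------------------- codon-aware alignment


def codon_align(cds_a: str, cds_b: str) -> tuple[str, str]:
    """Back-thread nucleotide triplets through a global protein alignment;
    codon columns opposite a gap are dropped pairwise."""
    from Bio import Align
    from Bio.Align import substitution_matrices

    from .models import translate

    prot_a, prot_b = translate(cds_a), translate(cds_b)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    aln = aligner.align(prot_a, prot_b)[0]
    ga, gb = str(aln[0]), str(aln[1])
    ia = ib = 0
    out_a, out_b = [], []
    for ca, cb in zip(ga, gb):
        if ca != "-" and cb != "-":
            out_a.append(cds_a[3 * ia:3 * ia + 3])
            out_b.append(cds_b[3 * ib:3 * ib + 3])
        if ca != "-":
            ia += 1
        if cb != "-":
            ib += 1
    return "".join(out_a), "".join(out_b)


def pairwise_omega(cds_a: str, cds_b: str) -> DnDsResult:
    """NG86 on the codon alignment of two coding sequences."""
    a, b = codon_align(cds_a, cds_b)
    return ng86(a, b)


def clade_omega(
    ortholog_cds: Sequence[Mapping[str, str]],
    clade_map: Mapping[str, str],
    n_perm: int = 999,
    seed: Optional[int] = None,
) -> tuple[pd.DataFrame, float, float]:
    """Per-clade omega distributions from within-clade ortholog pairs, plus
    a Mann-Whitney comparison with a permutation p-value.

    ``ortholog_cds`` is one mapping genome -> CDS per ortholog group.
    Raises ValueError when any clade yields fewer than 2 omega values.
    """
    rows = []
    for gi, grp in enumerate(ortholog_cds):
        by_clade: dict[str, list[str]] = {}
        for genome, cds in grp.items():
            by_clade.setdefault(clade_map[genome], []).append(genome)
        for clade, members in by_clade.items():
            members = sorted(members)
            for i, a in enumerate(members):
                for b in members[i + 1:]:
                    try:
                        res = pairwise_omega(grp[a], grp[b])
                    except ValueError:
                        continue
                    if res.omega is not None and np.isfinite(res.omega):
                        rows.append((gi, clade, a, b, res.omega))
    table = pd.DataFrame(rows, columns=["group", "clade", "genome_a",
                                        "genome_b", "omega"])
    clades = sorted(set(clade_map.values()))
    if len(clades) != 2:
        raise ValueError("clade omega comparison needs exactly 2 clades")
    w_a = table.loc[table.clade == clades[0], "omega"].to_numpy()
    w_b = table.loc[table.clade == clades[1], "omega"].to_numpy()
    if len(w_a) < 2 or len(w_b) < 2:
        raise ValueError("insufficient omega values per clade (need >= 2)")
    u_stat = stats.mannwhitneyu(w_a, w_b, alternative="two-sided").statistic
    pooled = np.concatenate([w_a, w_b])
    rng = np.random.default_rng(seed)
    count = 0
    obs = abs(np.median(w_a) - np.median(w_b))
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        d = abs(np.median(perm[:len(w_a)]) - np.median(perm[len(w_a):]))
        if d >= obs:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return table, float(u_stat), float(p)


def orfan_copy_enrichment(
    membership: pd.DataFrame, orfan_clusters: set[str]
) -> tuple[np.ndarray, float]:
    """Fisher exact test of the single-copy x ORFan-family contingency:
    ORFan genes duplicate less often. Returns (2x2 table, p-value)."""
    sizes = membership.groupby(["genome_id", "cluster_id"])["gene_id"].transform("count")
    is_multi = (sizes >= 2).to_numpy()
    is_orfan = membership["cluster_id"].isin(orfan_clusters).to_numpy()
    table = np.array([
        [int(np.sum(~is_multi & is_orfan)), int(np.sum(~is_multi & ~is_orfan))],
        [int(np.sum(is_multi & is_orfan)), int(np.sum(is_multi & ~is_orfan))],
    ])
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return table, float(p)
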
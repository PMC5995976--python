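"""Core/pan-genome openness statistics and gene category assignment.

The pan-genome curve is a rarefaction over random genome orderings; openness
is summarized by a Heaps-law fit on the mean number of new gene families per
added genome, dP(N) = kappa * N^(-alpha), where alpha < 1 indicates an open
pan-genome. Genomic fluidity phi is the average over genome pairs of the
fraction of genes belonging to families not shared by the pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


@dataclass
class PanGenomeCurve:
    genomes: list[str]
    pan: np.ndarray          # (n_perm, G) cumulative pan size per ordering
    core: np.ndarray         # (n_perm, G) cumulative core size per ordering
    n_perm: int
    seed: Optional[int]

    def summary(self) -> pd.DataFrame:
        rows = []
        for j in range(self.pan.shape[1]):
            for name, arr in (("pan", self.pan[:, j]), ("core", self.core[:, j])):
                rows.append(dict(
                    N=j + 1, stat=name,
                    median=float(np.median(arr)),
                    q25=float(np.percentile(arr, 25)),
                    q75=float(np.percentile(arr, 75)),
                    min=float(arr.min()), max=float(arr.max()),
                ))
        return pd.DataFrame(rows)

    def mean_new_clusters(self) -> np.ndarray:
        """Mean number of clusters first seen at step N, for N = 2..G."""
        increments = np.diff(self.pan, axis=1)
        return increments.mean(axis=0)


@dataclass
class HeapsFit:
    kappa: float
    alpha: float
    residuals: np.ndarray
    open_pangenome: bool = field(init=False)

    def __post_init__(self) -> None:
        self.open_pangenome = self.alpha < 1.0


@dataclass
class FluidityEstimate:
    phi: float
    pairwise: pd.DataFrame   # genome_a, genome_b, phi
    jackknife_variance: float


def _presence(membership: pd.DataFrame) -> dict[str, set[str]]:
    """genome -> set of cluster ids present."""
    return {
        g: set(sub["cluster_id"]) for g, sub in membership.groupby("genome_id")
    }


def rarefaction(
    membership: pd.DataFrame,
    n_perm: int = 1000,
    seed: Optional[int] = None,
    orderings: Optional[list[list[str]]] = None,
) -> PanGenomeCurve:
    """Pan/core rarefaction over random genome orderings.

    ``membership`` is the long-form (gene_id, genome_id, cluster_id) table.
    ``orderings`` overrides the random permutations (used for exhaustive
    enumeration on small genome sets).
    """
    presence = _presence(membership)
    genomes = sorted(presence)
    if len(genomes) < 2:
        raise ValueError("rarefaction needs at least 2 genomes")
    rng = np.random.default_rng(seed)
    if orderings is None:
        orderings = [list(rng.permutation(genomes)) for _ in range(n_perm)]
    pan = np.zeros((len(orderings), len(genomes)), dtype=int)
    core = np.zeros_like(pan)
    for i, order in enumerate(orderings):
        acc_pan: set[str] = set()
        acc_core: Optional[set[str]] = None
        for j, g in enumerate(order):
            acc_pan |= presence[g]
            acc_core = set(presence[g]) if acc_core is None else acc_core & presence[g]
            pan[i, j] = len(acc_pan)
            core[i, j] = len(acc_core)
    return PanGenomeCurve(genomes=genomes, pan=pan, core=core,
                          n_perm=len(orderings), seed=seed)


def fit_heaps(curve: PanGenomeCurve) -> HeapsFit:
    """Nonlinear least squares of dP(N) = kappa * N^(-alpha) on the mean
    new-cluster counts for N >= 2 (micropan-style openness fit)."""
    if len(curve.genomes) < 3:
        raise ValueError("Heaps fit needs at least 3 genomes")
    n = np.arange(2, len(curve.genomes) + 1, dtype=float)
    dp = curve.mean_new_clusters()
    if np.all(dp <= 0):
        # closed pan-genome: no new clusters after the first genome
        return HeapsFit(kappa=0.0, alpha=np.inf, residuals=np.zeros_like(dp))

    def model(nn: np.ndarray, kappa: float, alpha: float) -> np.ndarray:
        return kappa * np.power(nn, -alpha)

    p0 = (max(dp[0], 1.0), 0.5)
    popt, _ = curve_fit(model, n, dp, p0=p0, maxfev=20000)
    kappa, alpha = float(popt[0]), float(popt[1])
    return HeapsFit(kappa=kappa, alpha=alpha, residuals=dp - model(n, *popt))


def fluidity(membership: pd.DataFrame) -> FluidityEstimate:
    """Genomic fluidity phi = mean over genome pairs of
    (U_k + U_l) / (M_k + M_l), where U counts genes in clusters absent from
    the partner genome and M counts all genes. Variance by jackknife over
    genomes (0 when fewer than 3 genomes)."""
    presence = _presence(membership)
    genomes = sorted(presence)
    if len(genomes) < 2:
        raise ValueError("fluidity needs at least 2 genomes")
    genes_per_genome = membership.groupby("genome_id")["gene_id"].count()

    def pair_phi(a: str, b: str) -> float:
        sub_a = membership[membership["genome_id"] == a]
        sub_b = membership[membership["genome_id"] == b]
        u_a = int((~sub_a["cluster_id"].isin(presence[b])).sum())
        u_b = int((~sub_b["cluster_id"].isin(presence[a])).sum())
        m = int(genes_per_genome[a] + genes_per_genome[b])
        return (u_a + u_b) / m

    rows = []
    for i, a in enumerate(genomes):
        for b in genomes[i + 1:]:
            rows.append((a, b, pair_phi(a, b)))
    pairwise = pd.DataFrame(rows, columns=["genome_a", "genome_b", "phi"])
    phi = float(pairwise["phi"].mean())

    if len(genomes) >= 3:
        loo = []
        for g in genomes:
            keep = pairwise[(pairwise.genome_a != g) & (pairwise.genome_b != g)]
            loo.append(keep["phi"].mean())
        loo_arr = np.asarray(loo)
        n = len(genomes)
        jk_var = float((n - 1) / n * np.sum((loo_arr - loo_arr.mean()) ** 2))
    else:
        jk_var = 0.0
    return FluidityEstimate(phi=phi, pairwise=pairwise, jackknife_variance=jk_var)


def categorize(
    membership: pd.DataFrame,
    clade_map: Mapping[str, str],
) -> pd.DataFrame:
    """Assign core / clade_specific / strain_specific / accessory to every
    cluster and gene.

    core: present in all genomes; clade_specific: present in every member of
    exactly one clade (of >= 2 genomes) and nowhere else; strain_specific:
    present in exactly one genome; accessory: anything else.
    """
    genomes = sorted(set(membership["genome_id"]))
    missing = set(genomes) - set(clade_map)
    if missing:
        raise ValueError(f"clade_map lacks genomes: {sorted(missing)}")
    clades: dict[str, set[str]] = {}
    for g in genomes:
        clades.setdefault(clade_map[g], set()).add(g)
    cat: dict[str, str] = {}
    for cluster_id, sub in membership.groupby("cluster_id"):
        present = set(sub["genome_id"])
        if present == set(genomes):
            cat[cluster_id] = "core"
        elif len(present) == 1:
            cat[cluster_id] = "strain_specific"
        elif any(present == members and len(members) >= 2
                 for members in clades.values()):
            cat[cluster_id] = "clade_specific"
        else:
            cat[cluster_id] = "accessory"
    out = membership.copy()
    out["category"] = out["cluster_id"].map(cat)
    return out


def sharing_spectrum(membership: pd.DataFrame) -> pd.DataFrame:
    """Numbers of clusters and genes shared by exactly k genomes."""
    per_cluster = membership.groupby("cluster_id").agg(
        n_genomes=("genome_id", "nunique"), n_genes=("gene_id", "count")
    )
    out = per_cluster.groupby("n_genomes").agg(
        n_clusters=("n_genes", "count"), n_genes=("n_genes", "sum")
    ).reset_index()
    return out.sort_values("n_genomes", ascending=False).reset_index(drop=True)
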
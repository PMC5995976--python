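"""Virion proteome analysis from iBAQ abundance tables.

Proteins are ranked by mean iBAQ (after per-replicate total normalization);
the retained particle proteome is either the top-k proteins (k = 200 by
default, the rank where host-contaminant identifications start to pile up)
or an automatically detected change-point in the cumulative host-protein
count. The core proteome is the set of protein clusters hit by the retained
sets of all strains.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class RankedProteome:
    table: pd.DataFrame          # protein_id, source, mean_ibaq, rank
    retained: list[str]
    cutoff_rank: int
    host_fraction_above: float
    host_fraction_below: float


def _replicate_columns(table: pd.DataFrame) -> list[str]:
    cols = [c for c in table.columns if c.startswith("ibaq")]
    if not cols:
        raise ValueError("no iBAQ replicate columns (expected ibaq* names)")
    return cols


def rank_proteins(table: pd.DataFrame) -> pd.DataFrame:
    """Mean iBAQ across total-normalized replicates, ranked descending;
    ties broken by protein_id so ranks are 1..n and deterministic."""
    cols = _replicate_columns(table)
    norm = table[cols].to_numpy(dtype=float)
    totals = norm.sum(axis=0)
    norm = norm / totals * totals.mean()
    out = table.copy()
    out["mean_ibaq"] = norm.mean(axis=1)
    out = out.sort_values(
        ["mean_ibaq", "protein_id"], ascending=[False, True]
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def _changepoint_cut(ranked: pd.DataFrame) -> int:
    """Rank at which the slope of the cumulative host-protein count
    increases most (two-segment least-squares fit)."""
    is_host = (ranked["source"] == "host").to_numpy(dtype=float)
    n = len(is_host)
    cum = np.cumsum(is_host)
    best_k, best_sse = n, np.inf
    x = np.arange(1, n + 1, dtype=float)
    for k in range(max(n // 10, 2), n - 2):
        sse = 0.0
        for sl in (slice(0, k), slice(k, n)):
            xs, ys = x[sl], cum[sl]
            xm, ym = xs.mean(), ys.mean()
            denom = np.sum((xs - xm) ** 2)
            slope = np.sum((xs - xm) * (ys - ym)) / denom if denom else 0.0
            resid = ys - (ym + slope * (xs - xm))
            sse += float(np.sum(resid ** 2))
        if sse < best_sse:
            best_sse, best_k = sse, k
    return best_k


def rank_and_cut(
    table: pd.DataFrame, method: str = "fixed", k: int = 200
) -> RankedProteome:
    """Rank by mean iBAQ and retain the particle proteome.

    method="fixed": top-k proteins. method="auto": cut at the detected
    change-point of host-protein accumulation.
    """
    ranked = rank_proteins(table)
    if method == "fixed":
        cut = min(k, len(ranked))
    elif method == "auto":
        cut = _changepoint_cut(ranked)
    else:
        raise ValueError(f"unknown cutoff method {method!r}")
    retained = ranked.loc[ranked["rank"] <= cut, "protein_id"].tolist()
    above = ranked[ranked["rank"] <= cut]
    below = ranked[ranked["rank"] > cut]
    host_above = float((above["source"] == "host").mean()) if len(above) else 0.0
    host_below = float((below["source"] == "host").mean()) if len(below) else 0.0
    return RankedProteome(
        table=ranked, retained=retained, cutoff_rank=cut,
        host_fraction_above=host_above, host_fraction_below=host_below,
    )


def core_proteome(
    retained: Mapping[str, Sequence[str]],
    cluster_of: Mapping[str, str],
) -> tuple[pd.DataFrame, float]:
    """Partition proteome clusters by the subset of strains whose retained
    sets hit them; returns (partition table, core fraction).

    Host or unmapped proteins (absent from ``cluster_of``) are ignored.
    The core fraction is shared-by-all clusters / total clusters.
    """
    strains = sorted(retained)
    hits: dict[str, set[str]] = {}
    for strain in strains:
        for pid in retained[strain]:
            cl = cluster_of.get(pid)
            if cl is not None:
                hits.setdefault(cl, set()).add(strain)
    rows = [
        (cl, ",".join(sorted(ss)), len(ss), len(ss) == len(strains))
        for cl, ss in sorted(hits.items())
    ]
    df = pd.DataFrame(rows, columns=["cluster_id", "strains", "n_strains",
                                     "shared_by_all"])
    total = len(df)
    shared = int(df["shared_by_all"].sum()) if total else 0
    return df, (shared / total if total else float("nan"))


def abundance_correlation(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    pairing: Optional[Mapping[str, str]] = None,
) -> tuple[float, int, int]:
    """Pearson r on log10 mean iBAQ of paired proteins.

    Pairing defaults to identical protein ids (replicate/biological
    comparisons); a mapping a_id -> b_id pairs orthologs across strains.
    Pairs with non-positive abundance on either side are dropped and
    counted. Returns (r, n_used, n_dropped).
    """
    a = rank_proteins(table_a).set_index("protein_id")["mean_ibaq"]
    b = rank_proteins(table_b).set_index("protein_id")["mean_ibaq"]
    if pairing is None:
        keys = sorted(set(a.index) & set(b.index))
        pairs = [(k, k) for k in keys]
    else:
        pairs = [(ka, kb) for ka, kb in sorted(pairing.items())
                 if ka in a.index and kb in b.index]
    xs, ys, dropped = [], [], 0
    for ka, kb in pairs:
        va, vb = float(a[ka]), float(b[kb])
        if va > 0 and vb > 0:
            xs.append(np.log10(va))
            ys.append(np.log10(vb))
        else:
            dropped += 1
    if len(xs) < 10:
        raise ValueError("need at least 10 positive abundance pairs")
    r = stats.pearsonr(xs, ys).statistic
    return float(r), len(xs), dropped
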
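"""Collinear-block detection between genome pairs from ortholog positions.

Chaining works on gene rank (order index along the chromosome), not on bp
distance, which makes it robust to the large length differences between
related genomes. A block is a maximal run of ortholog pairs whose ranks move
consistently in both genomes (same or inverted orientation) with at most
``max_gap`` intervening non-matching genes on either genome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass
class SyntenyBlock:
    genome_a: str
    genome_b: str
    pairs: list[tuple[str, str]]     # ordered ortholog pairs (gene_a, gene_b)
    orientation: str                 # "same" | "inverted"

    def __len__(self) -> int:
        return len(self.pairs)


def _ranks(order: Sequence[str]) -> dict[str, int]:
    return {g: i for i, g in enumerate(order)}


def collinear_blocks(
    ortholog_pairs: Sequence[tuple[str, str]],
    order_a: Sequence[str],
    order_b: Sequence[str],
    max_gap: int = 5,
    min_block: int = 3,
    genome_a: str = "a",
    genome_b: str = "b",
) -> list[SyntenyBlock]:
    """Greedy rank chaining of ortholog pairs.

    Pairs are visited in genome-a rank order; a chain extends while the
    a-rank and b-rank steps are both within max_gap+1 and the b-rank
    direction matches the chain orientation (fixed by the first step).
    Chains shorter than ``min_block`` are dropped. Blocks never share an
    ortholog pair.
    """
    rank_a = _ranks(order_a)
    rank_b = _ranks(order_b)
    pairs = sorted(
        [(rank_a[a], rank_b[b], a, b) for a, b in ortholog_pairs
         if a in rank_a and b in rank_b]
    )
    blocks: list[SyntenyBlock] = []
    chain: list[tuple[int, int, str, str]] = []
    direction = 0

    def flush() -> None:
        nonlocal chain, direction
        if len(chain) >= min_block:
            blocks.append(SyntenyBlock(
                genome_a=genome_a, genome_b=genome_b,
                pairs=[(a, b) for _, _, a, b in chain],
                orientation="same" if direction >= 0 else "inverted",
            ))
        chain, direction = [], 0

    for ra, rb, a, b in pairs:
        if not chain:
            chain = [(ra, rb, a, b)]
            continue
        pa, pb, _, _ = chain[-1]
        da, db = ra - pa, rb - pb
        step_ok = 0 < da <= max_gap + 1 and 0 < abs(db) <= max_gap + 1
        dir_ok = direction == 0 or np.sign(db) == direction
        if step_ok and dir_ok:
            chain.append((ra, rb, a, b))
            if direction == 0:
                direction = int(np.sign(db))
        else:
            flush()
            chain = [(ra, rb, a, b)]
    flush()
    return blocks


def collinearity_fraction(
    blocks: Sequence[SyntenyBlock],
    ortholog_pairs: Sequence[tuple[str, str]],
) -> float:
    """Fraction of ortholog pairs assigned to any collinear block (inverted
    blocks count as collinear)."""
    if not ortholog_pairs:
        return float("nan")
    in_block = {p for b in blocks for p in b.pairs}
    return len(in_block & set(map(tuple, ortholog_pairs))) / len(ortholog_pairs)


def pairwise_collinearity(
    groups: Sequence[Mapping[str, str]],
    orders: Mapping[str, Sequence[str]],
    max_gap: int = 5,
    min_block: int = 3,
) -> tuple[pd.DataFrame, dict[tuple[str, str], list[SyntenyBlock]]]:
    """Collinearity fraction for every genome pair from ortholog groups,
    plus the blocks themselves. The family-level figure is the mean over
    pairs of the per-pair fractions."""
    genomes = sorted(orders)
    rows = []
    all_blocks: dict[tuple[str, str], list[SyntenyBlock]] = {}
    for i, ga in enumerate(genomes):
        for gb in genomes[i + 1:]:
            pairs = [
                (grp[ga], grp[gb]) for grp in groups if ga in grp and gb in grp
            ]
            blocks = collinear_blocks(
                pairs, orders[ga], orders[gb], max_gap=max_gap,
                min_block=min_block, genome_a=ga, genome_b=gb,
            )
            all_blocks[(ga, gb)] = blocks
            rows.append((ga, gb, len(pairs),
                         collinearity_fraction(blocks, pairs)))
    df = pd.DataFrame(rows, columns=["genome_a", "genome_b", "n_orthologs",
                                     "collinear_fraction"])
    return df, all_blocks


def blocks_table(all_blocks: Mapping[tuple[str, str], Sequence[SyntenyBlock]]) -> pd.DataFrame:
    rows = []
    for (ga, gb), blocks in sorted(all_blocks.items()):
        for i, blk in enumerate(blocks, 1):
            rows.append((ga, gb, f"{ga}-{gb}-b{i:03d}", blk.orientation,
                         len(blk), ",".join(a for a, _ in blk.pairs)))
    return pd.DataFrame(rows, columns=["genome_a", "genome_b", "block_id",
                                       "orientation", "n_pairs", "members_a"])


def core_density_profile(
    ordered_categories: Sequence[str],
    window: int = 51,
) -> tuple[np.ndarray, int, float]:
    """Sliding-window core-gene frequency along the gene order, plus a
    two-segment change-point statistic.

    Returns (profile, split_index, delta) where delta is the difference in
    core density between the two segments at the best split (the split
    maximizing |mean_left - mean_right|, ties to the leftmost). A window
    larger than the gene count collapses to the single overall frequency.
    """
    is_core = np.asarray([c == "core" for c in ordered_categories], dtype=float)
    n = len(is_core)
    if n == 0:
        return np.array([]), 0, 0.0
    if window >= n:
        return np.array([is_core.mean()]), 0, 0.0
    kernel = np.ones(window) / window
    profile = np.convolve(is_core, kernel, mode="valid")
    best_split, best_delta = 0, 0.0
    csum = np.cumsum(is_core)
    for k in range(1, n):
        left = csum[k - 1] / k
        right = (csum[-1] - csum[k - 1]) / (n - k)
        delta = abs(left - right)
        if delta > best_delta + 1e-12:
            best_delta, best_split = delta, k
    if best_split == 0:  # homogeneous sequence: no change point
        return profile, 0, 0.0
    left = csum[best_split - 1] / best_split
    right = (csum[-1] - csum[best_split - 1]) / (n - best_split)
    return profile, best_split, float(left - right)
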
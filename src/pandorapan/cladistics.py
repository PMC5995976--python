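"""Gene-content cladistics and super-alignment similarity.

The presence/absence of protein clusters across taxa feeds a Jaccard
distance matrix and a neighbor-joining tree; branch support comes from
bootstrap resampling of clusters (matrix columns). Pairwise sequence
similarity between taxa is computed from concatenated ortholog-group
alignments ("super alignment"): percent identical columns and percent
positively scoring (BLOSUM62) columns.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj


def build_matrix(membership: pd.DataFrame) -> pd.DataFrame:
    """Taxa x clusters presence/absence matrix (entry 1 iff the taxon has
    at least one member in the cluster). Columns sorted; no all-zero
    columns can arise by construction."""
    mat = (
        membership.assign(present=1)
        .pivot_table(index="genome_id", columns="cluster_id",
                     values="present", aggfunc="max", fill_value=0)
    )
    return mat.sort_index(axis=0).sort_index(axis=1).astype(int)


def jaccard_distances(matrix: pd.DataFrame) -> DistanceMatrix:
    d = pdist(matrix.to_numpy(dtype=bool), metric="jaccard")
    return DistanceMatrix(squareform(d), ids=list(matrix.index))


def _bipartitions(tree: TreeNode, taxa: frozenset[str]) -> set[frozenset[str]]:
    """Non-trivial bipartitions as the smaller/canonical side of each
    internal edge."""
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(taxa) - 1:
            other = taxa - side
            out.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return out


def content_tree(
    matrix: pd.DataFrame,
    n_bootstrap: int = 100,
    seed: Optional[int] = None,
) -> tuple[TreeNode, dict[frozenset[str], float]]:
    """Neighbor-joining tree on Jaccard distances between presence/absence
    rows, with bootstrap support (fraction of column-resampled replicates
    containing each bipartition of the main tree)."""
    if len(matrix) < 4:
        raise ValueError("content tree needs at least 4 taxa")
    taxa = frozenset(matrix.index)
    main = nj(jaccard_distances(matrix))
    main_bips = _bipartitions(main, taxa)
    support = {bip: 0.0 for bip in main_bips}
    rng = np.random.default_rng(seed)
    ncols = matrix.shape[1]
    for _ in range(n_bootstrap):
        cols = rng.integers(0, ncols, size=ncols)
        boot = matrix.iloc[:, cols]
        btree = nj(jaccard_distances(boot))
        bbips = _bipartitions(btree, taxa)
        for bip in main_bips & bbips:
            support[bip] += 1.0
    if n_bootstrap > 0:
        support = {k: v / n_bootstrap for k, v in support.items()}
    # annotate internal nodes with their support values
    for node in main.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = taxa - side
        key = min(side, other, key=lambda s: (len(s), sorted(s)))
        if key in support:
            node.name = f"{support[key]:.2f}"
    return main, support


def tree_newick(tree: TreeNode) -> str:
    return str(tree).strip()


_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _make_global_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _BLOSUM62
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def superalignment_similarity(
    ortholog_groups: Sequence[Mapping[str, str]],
    alignments: Optional[Sequence[Mapping[str, str]]] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise percent identity and percent similarity matrices from
    concatenated ortholog alignments.

    ``ortholog_groups`` holds one genome->protein mapping per group. When
    ``alignments`` (genome -> aligned sequence with gaps, equal lengths per
    group) is not supplied, each taxon pair is aligned globally per group
    and columns are pooled over all groups containing both taxa — for a
    pair of taxa this equals a per-pair super alignment.

    Similarity counts columns whose residue pair scores positively in
    BLOSUM62 (identities included); identity counts exact matches. Both are
    percentages of ungapped aligned columns.
    """
    taxa = sorted({t for grp in ortholog_groups for t in grp})
    ident = np.full((len(taxa), len(taxa)), 100.0)
    simil = np.full((len(taxa), len(taxa)), 100.0)
    aligner = _make_global_aligner()
    for i, ta in enumerate(taxa):
        for j in range(i + 1, len(taxa)):
            tb = taxa[j]
            n_cols = n_id = n_pos = 0
            for gi, grp in enumerate(ortholog_groups):
                if ta not in grp or tb not in grp:
                    continue
                if alignments is not None:
                    ga, gb = alignments[gi][ta], alignments[gi][tb]
                else:
                    aln = aligner.align(grp[ta], grp[tb])[0]
                    ga, gb = str(aln[0]), str(aln[1])
                for ca, cb in zip(ga, gb):
                    if ca == "-" or cb == "-":
                        continue
                    n_cols += 1
                    if ca == cb:
                        n_id += 1
                    try:
                        if _BLOSUM62[ca, cb] > 0:
                            n_pos += 1
                    except IndexError:
                        pass
            if n_cols:
                ident[i, j] = ident[j, i] = 100.0 * n_id / n_cols
                simil[i, j] = simil[j, i] = 100.0 * n_pos / n_cols
            else:
                ident[i, j] = ident[j, i] = float("nan")
                simil[i, j] = simil[j, i] = float("nan")
    return (pd.DataFrame(ident, index=taxa, columns=taxa),
            pd.DataFrame(simil, index=taxa, columns=taxa))
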
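"""Statistical battery for the origin of lineage-restricted genes.

The analyses here ask whether strain-specific genes look like young genes
born from non-coding sequence: positional context within otherwise
collinear gene neighbourhoods, a composition gradient (GC, ORF length, CAI)
from core genes down to intergenic sequence, direct homology between a
strain-specific gene and a non-coding region at the homologous location in
a sister strain, an intrinsic-disorder proxy, and an automated gene-tree
rule separating ancestral presence from horizontal acquisition or donation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotate import CodonUsageTable, compute_cai
from .models import GeneModel, Genome, gc_content, revcomp, translate


# ------------------------------------------------------ positional filter


def positional_filter(
    ordered_genes: Sequence[GeneModel],
    categories: Mapping[str, str],
    block_members: set[str],
    max_flank: int = 3,
) -> pd.DataFrame:
    """Flag strain-specific genes found interspersed within otherwise
    collinear runs of core/clade-specific genes.

    A strain-specific gene passes when, within ``max_flank`` annotated
    neighbours on each side, there is a collinear-block ortholog of
    category core or clade_specific. Genes at a chromosome terminus (one
    flank missing entirely) fail.
    """
    ids = [g.id for g in ordered_genes]
    rows = []
    for i, g in enumerate(ordered_genes):
        if categories.get(g.id) != "strain_specific":
            continue
        def flank_ok(indices) -> bool:
            found = False
            for j in indices:
                gid = ids[j]
                if gid in block_members and categories.get(gid) in (
                    "core", "clade_specific"
                ):
                    found = True
                    break
            return found
        left = range(i - 1, max(i - 1 - max_flank, -1), -1)
        right = range(i + 1, min(i + 1 + max_flank, len(ids)))
        ok = len(list(left)) > 0 and len(list(right)) > 0 \
            and flank_ok(left) and flank_ok(right)
        rows.append((g.id, g.genome_id, bool(ok)))
    return pd.DataFrame(rows, columns=["gene_id", "genome_id",
                                       "positional_context_ok"])


# ------------------------------------------------------- feature gradient


def gene_feature_rows(
    genes: Sequence[GeneModel],
    genome: Genome,
    categories: Mapping[str, str],
    usage: CodonUsageTable,
) -> pd.DataFrame:
    """Per-gene GC content, ORF length (nt, spliced), and CAI."""
    rows = []
    for g in genes:
        if g.kind != "CDS":
            continue
        cds = g.coding_sequence(genome)
        rows.append((
            g.id, g.genome_id, categories.get(g.id, "unassigned"),
            gc_content(cds), len(cds), compute_cai(cds, usage),
        ))
    return pd.DataFrame(rows, columns=["gene_id", "genome_id", "category",
                                       "gc", "length_nt", "cai"])


def intergenic_feature_rows(
    genome: Genome,
    genes: Sequence[GeneModel],
    usage: CodonUsageTable,
    min_orf_len: int = 150,
    max_samples: int = 500,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """The intergenic baseline: random ORFs (ATG..stop, >= min_orf_len)
    found in the intergenic complement of the annotation, scored with the
    same GC/length/CAI features as real genes."""
    from .annotate import call_orfs
    from .models import merge_intervals

    spans = merge_intervals([(g.start, g.end) for g in genes])
    rng = np.random.default_rng(seed)
    rows = []
    prev = 0
    regions = []
    for s, e in spans + [(len(genome), len(genome))]:
        if s - prev >= min_orf_len:
            regions.append((prev, s))
        prev = max(prev, e)
    n_reg = 0
    for s, e in regions:
        sub = Genome(id=f"ig_{s}", sequence=genome.sequence[s:e])
        try:
            orfs = call_orfs(sub, max(min_orf_len, 60))
        except ValueError:
            continue
        for orf in orfs:
            cds = orf.coding_sequence(sub)
            rows.append((f"ig_{s}_{orf.start}", genome.id, "intergenic",
                         gc_content(cds), len(cds), compute_cai(cds, usage)))
            n_reg += 1
    df = pd.DataFrame(rows, columns=["gene_id", "genome_id", "category",
                                     "gc", "length_nt", "cai"])
    if len(df) > max_samples:
        df = df.sample(n=max_samples, random_state=rng.integers(2**31)).reset_index(drop=True)
    return df


_GRADIENT_ORDER = ["core", "clade_specific", "strain_specific", "intergenic"]


def gradient_test(
    feature_rows: pd.DataFrame,
    intergenic_rows: pd.DataFrame,
    min_n: int = 5,
) -> pd.DataFrame:
    """Category medians, adjacent-pair Mann-Whitney tests (BH-corrected),
    and a monotonic-gradient verdict for each of GC, ORF length, and CAI.

    The verdict is "gradient" when the category medians decrease strictly
    from core through clade-specific and strain-specific genes down to
    intergenic sequence, "reversed" when they increase strictly, and
    "no_gradient" otherwise; "insufficient_n" when any category is smaller
    than ``min_n``.
    """
    data = pd.concat([feature_rows, intergenic_rows], ignore_index=True)
    out_rows = []
    for feature in ("gc", "length_nt", "cai"):
        groups = {
            cat: data.loc[data.category == cat, feature].to_numpy(dtype=float)
            for cat in _GRADIENT_ORDER
        }
        medians = {cat: (float(np.median(v)) if len(v) else float("nan"))
                   for cat, v in groups.items()}
        if any(len(groups[cat]) < min_n for cat in _GRADIENT_ORDER):
            verdict = "insufficient_n"
            pvals = [float("nan")] * 3
            padj = pvals
        else:
            pvals = []
            for a, b in zip(_GRADIENT_ORDER, _GRADIENT_ORDER[1:]):
                p = stats.mannwhitneyu(groups[a], groups[b],
                                       alternative="two-sided").pvalue
                pvals.append(float(p))
            padj = list(multipletests(pvals, method="fdr_bh")[1])
            m = [medians[c] for c in _GRADIENT_ORDER]
            if all(x > y for x, y in zip(m, m[1:])):
                verdict = "gradient"
            elif all(x < y for x, y in zip(m, m[1:])):
                verdict = "reversed"
            else:
                verdict = "no_gradient"
        row = dict(feature=feature, verdict=verdict)
        for cat in _GRADIENT_ORDER:
            row[f"median_{cat}"] = medians[cat]
        for (a, b), p, q in zip(
            zip(_GRADIENT_ORDER, _GRADIENT_ORDER[1:]), pvals, padj
        ):
            row[f"p_{a}_vs_{b}"] = p
            row[f"q_{a}_vs_{b}"] = q
        out_rows.append(row)
    return pd.DataFrame(out_rows)


# -------------------------------------------------------- intergenic scan


@dataclass
class SubjectRegion:
    region_id: str
    genome_id: str
    kind: str                # "intergenic" | "ncRNA"
    start: int
    end: int
    sequence: str


def subject_regions_from_annotation(
    genome: Genome, genes: Sequence[GeneModel], min_len: int = 60
) -> list[SubjectRegion]:
    """Intergenic complement of the CDS annotation plus annotated ncRNAs."""
    from .models import merge_intervals

    cds_spans = merge_intervals(
        [(g.start, g.end) for g in genes if g.kind == "CDS"]
    )
    regions = []
    prev = 0
    for s, e in cds_spans + [(len(genome), len(genome))]:
        if s - prev >= min_len:
            regions.append(SubjectRegion(
                f"{genome.id}_ig_{prev}", genome.id, "intergenic",
                prev, s, genome.sequence[prev:s],
            ))
        prev = max(prev, e)
    for g in genes:
        if g.kind == "lncRNA":
            regions.append(SubjectRegion(
                g.id, genome.id, "ncRNA", g.start, g.end,
                genome.sequence[g.start:g.end],
            ))
    return regions


def _six_frame_best(protein: str, region_seq: str, aligner) -> tuple[float, str]:
    """Best local score of the protein against all six translated frames;
    returns (score, best frame's translation)."""
    best, best_target = 0.0, ""
    for seq in (region_seq, revcomp(region_seq)):
        for frame in range(3):
            sub = seq[frame:]
            sub = sub[:len(sub) - len(sub) % 3]
            if len(sub) < 30:
                continue
            target = translate(sub, trim_stop=False).replace("*", "X")
            if len(target) < 10:
                continue
            score = float(aligner.score(protein, target))
            if score > best:
                best, best_target = score, target
    return best, best_target


def _alignment_identity(protein: str, target: str, aligner) -> tuple[float, int]:
    aln = aligner.align(protein, target)[0]
    counts = aln.counts()
    cols = counts.identities + counts.mismatches + counts.gaps
    return (counts.identities / cols if cols else 0.0), cols


def intergenic_scan(
    query_genes: Mapping[str, str],
    subject_regions: Sequence[SubjectRegion],
    homologous_intervals: Optional[Mapping[str, Mapping[str, tuple[int, int]]]] = None,
    e_max: float = 1e-3,
    query_genome_of: Optional[Mapping[str, str]] = None,
    min_identity: float = 0.45,
    min_aligned: int = 25,
) -> pd.DataFrame:
    """Translated search of strain-specific query CDS against non-coding
    regions of other strains.

    ``query_genes`` maps gene_id -> CDS. ``homologous_intervals`` maps
    gene_id -> {subject_genome: (lo, hi)}: the interval between the subject
    orthologs of the query's flanking genes; a hit is flagged
    ``homologous_location`` when its region overlaps that interval.

    Besides the significance ceiling, hits must align at >= ``min_identity``
    over >= ``min_aligned`` columns: the GC-rich composition shared by query
    and subject inflates raw local scores, and the identity floor removes
    those composition-driven matches.
    """
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1

    rows = []
    for gene_id, cds in sorted(query_genes.items()):
        protein = translate(cds)
        own_genome = (query_genome_of or {}).get(gene_id)
        for region in subject_regions:
            if own_genome is not None and region.genome_id == own_genome:
                continue
            score, target = _six_frame_best(protein, region.sequence, aligner)
            if score <= 0:
                continue
            ev = 0.041 * len(protein) * max(len(region.sequence) // 3, 1) \
                * math.exp(-0.267 * score)
            if ev > e_max:
                continue
            identity, aligned = _alignment_identity(protein, target, aligner)
            if identity < min_identity or aligned < min_aligned:
                continue
            hom = False
            if homologous_intervals is not None:
                interval = homologous_intervals.get(gene_id, {}).get(region.genome_id)
                if interval is not None:
                    lo, hi = interval
                    hom = region.start < hi and region.end > lo
            rows.append((gene_id, region.genome_id, region.region_id,
                         region.kind, score, ev, hom))
    return pd.DataFrame(rows, columns=["query_gene", "subject_genome",
                                       "region_id", "region_kind", "score",
                                       "evalue", "homologous_location"])


# ----------------------------------------------------------- disorder


_KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}
_CHARGE = {"D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0, "H": 0.5}


def disorder_fraction(protein: str, window: int = 51) -> float:
    """Fraction of residues predicted disordered by a sliding-window
    charge-hydropathy index (FoldIndex-style):

        I = 2.785 * <H> - |<q>| - 1.151

    with <H> the mean Kyte-Doolittle hydropathy rescaled to [0, 1] and <q>
    the mean net charge; I < 0 marks the window's centre disordered.
    Proteins shorter than the window are scored as a single window.
    """
    if not protein:
        raise ValueError("empty protein")
    h = np.array([( _KYTE_DOOLITTLE.get(aa, 0.0) + 4.5) / 9.0 for aa in protein])
    q = np.array([_CHARGE.get(aa, 0.0) for aa in protein])
    n = len(protein)
    if n <= window:
        idx = 2.785 * h.mean() - abs(q.mean()) - 1.151
        return 1.0 if idx < 0 else 0.0
    kernel = np.ones(window) / window
    mh = np.convolve(h, kernel, mode="same")
    mq = np.convolve(q, kernel, mode="same")
    # renormalize the truncated edge windows
    counts = np.convolve(np.ones(n), kernel, mode="same")
    mh /= counts
    mq /= counts
    index = 2.785 * mh - np.abs(mq) - 1.151
    return float(np.mean(index < 0))


def compare_disorder(
    orfans: Sequence[str], non_orfans: Sequence[str], window: int = 51
) -> tuple[float, float, float]:
    """(median ORFan fraction, median non-ORFan fraction, Mann-Whitney p)."""
    f_a = [disorder_fraction(p, window) for p in orfans]
    f_b = [disorder_fraction(p, window) for p in non_orfans]
    p = stats.mannwhitneyu(f_a, f_b, alternative="greater").pvalue
    return float(np.median(f_a)), float(np.median(f_b)), float(p)


# ------------------------------------------------------- HGT topology


def classify_hgt(
    tree: "dendropy.Tree | str",
    labels: Mapping[str, str],
    min_embedding: int = 2,
) -> str:
    """Classify a gene tree as ancestral / acquired_by_family /
    donated_by_family / undecided from the placement of family tips among
    cellular and other-virus homologs.

    Rules: family tips monophyletic and attached near the root (fewer than
    ``min_embedding`` non-family lineages between the family clade and the
    root) -> ancestral; family clade nested deeply inside non-family
    lineages -> acquired_by_family; one or more non-family tips nested
    within the family clade (but not all of them) -> donated_by_family;
    anything else -> undecided.
    """
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    tree = tree.clone(depth=1)
    if len(tree.seed_node.child_nodes()) > 2:
        try:
            tree.reroot_at_midpoint(update_bipartitions=False)
        except (ValueError, AssertionError):
            pass
    tree.is_rooted = True
    tree.encode_bipartitions()

    def label_of(leaf) -> str:
        return labels[leaf.taxon.label]

    leaves = tree.leaf_nodes()
    fam_leaves = [l for l in leaves if label_of(l) == "family"]
    nonfam_leaves = [l for l in leaves if label_of(l) != "family"]
    if not fam_leaves or not nonfam_leaves:
        return "undecided"
    mrca = tree.mrca(taxa=[l.taxon for l in fam_leaves])
    inside = mrca.leaf_nodes()
    nonfam_inside = [l for l in inside if label_of(l) != "family"]
    if nonfam_inside:
        if len(nonfam_inside) < len(nonfam_leaves):
            return "donated_by_family"
        return "undecided"
    # family is monophyletic: count non-family lineages between it and root
    n_between = 0
    node = mrca
    while node.parent_node is not None:
        parent = node.parent_node
        for sib in parent.child_nodes():
            if sib is node:
                continue
            sib_labels = {label_of(l) for l in sib.leaf_nodes()}
            if "family" not in sib_labels:
                n_between += 1
        node = parent
    if n_between >= min_embedding + 1:
        return "acquired_by_family"
    return "ancestral"
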
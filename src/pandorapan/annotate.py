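"""Stringent evidence-based genome annotation.

Ab initio ORF calling over all six frames is deliberately permissive; the
stringent step then retains only ORFs supported by same-strand transcript
coverage, peptide-spectrum matches, or cross-strain protein similarity.
Transcribed islands not explained by a retained coding gene become lncRNAs;
splice junctions split exons; UTRs extend to the coverage boundary.

This mirrors the annotation strategy needed for GC-rich genomes, where
random ORFs above any length cutoff are common because stop codons are
AT-rich and therefore rare by chance.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .models import (
    EvidenceBundle,
    GeneModel,
    Genome,
    SENSE_CODONS,
    STOP_CODONS,
    _CODON_TABLE,
    merge_intervals,
    revcomp,
    union_length,
)


@dataclass
class AnnotationParams:
    """Evidence thresholds (all tunable; the defaults are conservative)."""

    min_orf_len: int = 300          # nt, incl. stop codon
    cov_min: float = 5.0            # reads, per-base same-strand depth
    frac_min: float = 0.8           # fraction of ORF span that must be covered
    pep_min: int = 2                # distinct peptides
    e_max: float = 1e-5             # homology significance ceiling
    j_min: int = 3                  # junction read support
    lncrna_min_len: int = 200
    utr_slack: int = 400            # bp of UTR allowance around a CDS
    utr_max: int = 2000
    overlap_resolve_frac: float = 0.5


@dataclass
class AnnotationReport:
    n_cds: int = 0
    n_lncrna: int = 0
    n_trna: int = 0
    fraction_transcribed: float = 0.0
    fraction_translated: float = 0.0
    n_ab_initio: int = 0
    n_discarded: int = 0
    discard_reasons: Counter = field(default_factory=Counter)
    n_genes_with_introns: int = 0
    intron_fraction: float = 0.0
    mean_introns_per_spliced_gene: float = 0.0
    discarded: pd.DataFrame = field(default_factory=pd.DataFrame)


# ------------------------------------------------------------- ORF calling


def _orfs_one_strand(seq: str, min_len: int, genome_id: str, strand: str,
                     glen: int, prefix: str) -> list[GeneModel]:
    """ORFs (first ATG after previous in-frame stop .. stop, inclusive) on
    the given sequence; coordinates mapped back to the forward strand."""
    out = []
    n = len(seq)
    for frame in range(3):
        i = frame
        orf_start = None
        while i + 3 <= n:
            codon = seq[i:i + 3]
            if orf_start is None:
                if codon == "ATG":
                    orf_start = i
            elif codon in STOP_CODONS:
                end = i + 3
                if end - orf_start >= min_len and "N" not in seq[orf_start:end]:
                    if strand == "+":
                        s, e = orf_start, end
                    else:
                        s, e = glen - end, glen - orf_start
                    out.append(GeneModel(
                        id=f"{prefix}_{s}_{e}_{strand}",
                        genome_id=genome_id, start=s, end=e, strand=strand,
                        kind="CDS", evidence={"ab_initio"},
                    ))
                orf_start = None
            i += 3
    return out


def call_orfs(genome: Genome, min_len_nt: int = 300) -> list[GeneModel]:
    """Scan all six frames for ATG..stop ORFs of at least ``min_len_nt``
    (stop codon included). Nested same-frame ORFs resolve to the longest
    (the first ATG after the previous stop). ORFs containing N are skipped.
    """
    if min_len_nt < 60:
        raise ValueError("min_len_nt must be >= 60")
    if len(genome) < min_len_nt:
        return []
    fwd = _orfs_one_strand(genome.sequence, min_len_nt, genome.id, "+",
                           len(genome), f"{genome.id}_orf")
    rev = _orfs_one_strand(revcomp(genome.sequence), min_len_nt, genome.id, "-",
                           len(genome), f"{genome.id}_orf")
    return sorted(fwd + rev, key=lambda g: (g.start, g.end, g.strand))


# ------------------------------------------------- evidence integration


def _coverage_supported(orf: GeneModel, ev: EvidenceBundle,
                        p: AnnotationParams) -> bool:
    cov = ev.coverage(orf.strand)[orf.start:orf.end]
    return float(np.mean(cov >= p.cov_min)) >= p.frac_min


def _peptide_index(peptides: Iterable[tuple[str, str, int]], k: int = 7):
    idx: dict[str, set[str]] = {}
    for _, pep, _ in peptides:
        if len(pep) >= k:
            idx.setdefault(pep[:k], set()).add(pep)
    return idx


def _peptides_in(translation: str, idx: Mapping[str, set[str]], k: int = 7) -> int:
    found: set[str] = set()
    for i in range(len(translation) - k + 1):
        for pep in idx.get(translation[i:i + k], ()):
            if translation.startswith(pep, i):
                found.add(pep)
    return len(found)


def integrate_evidence(
    orfs: Sequence[GeneModel],
    genome: Genome,
    evidence: EvidenceBundle,
    homology_hits: Optional[pd.DataFrame] = None,
    params: Optional[AnnotationParams] = None,
) -> tuple[list[GeneModel], AnnotationReport]:
    """Retain ORFs supported by transcription, peptides, or cross-strain
    homology; same-strand overlaps above the resolution threshold keep the
    better-supported (then longer) ORF.

    ``homology_hits`` columns: query_id, subject_id, subject_genome, evalue.
    Hits whose subject_genome equals the annotated genome are self-matches
    and cannot rescue an ORF.
    """
    p = params or AnnotationParams()
    pep_idx = _peptide_index(evidence.peptides)
    hom_ok: set[str] = set()
    if homology_hits is not None and len(homology_hits):
        ok = homology_hits[
            (homology_hits["evalue"] <= p.e_max)
            & (homology_hits["subject_genome"] != genome.id)
        ]
        hom_ok = set(ok["query_id"])

    retained: list[GeneModel] = []
    discarded_rows: list[tuple[str, str]] = []
    for orf in orfs:
        flags = set(orf.evidence)
        if _coverage_supported(orf, evidence, p):
            flags.add("transcript")
        if pep_idx and _peptides_in(orf.protein(genome), pep_idx) >= p.pep_min:
            flags.add("peptide")
        if orf.id in hom_ok:
            flags.add("homology")
        if flags & {"transcript", "peptide", "homology"}:
            g = GeneModel(
                id=orf.id, genome_id=orf.genome_id, start=orf.start,
                end=orf.end, strand=orf.strand, kind="CDS",
                exons=list(orf.exons), evidence=flags,
                attributes=dict(orf.attributes),
            )
            retained.append(g)
        else:
            discarded_rows.append((orf.id, "no_evidence"))

    retained, overlap_dropped = _resolve_same_strand_overlaps(retained, p)
    discarded_rows.extend((g.id, "overlap_resolved") for g in overlap_dropped)

    report = AnnotationReport(
        n_cds=len(retained),
        n_ab_initio=len(orfs),
        n_discarded=len(discarded_rows),
        discard_reasons=Counter(reason for _, reason in discarded_rows),
        discarded=pd.DataFrame(discarded_rows, columns=["orf_id", "reason"]),
    )
    return retained, report


def _evidence_strength(g: GeneModel) -> int:
    return len(g.evidence & {"transcript", "peptide", "homology"})


def _resolve_same_strand_overlaps(
    genes: list[GeneModel], p: AnnotationParams
) -> tuple[list[GeneModel], list[GeneModel]]:
    """Same-strand pairs overlapping more than the threshold fraction of the
    shorter gene keep the higher-evidence (then longer) member. Opposite
    strands are never resolved against each other."""
    order = sorted(
        genes, key=lambda g: (-_evidence_strength(g), -(g.end - g.start), g.id)
    )
    kept: list[GeneModel] = []
    dropped: list[GeneModel] = []
    for g in order:
        clash = False
        for k in kept:
            if k.strand != g.strand or k.genome_id != g.genome_id:
                continue
            ov = min(k.end, g.end) - max(k.start, g.start)
            if ov <= 0:
                continue
            shorter = min(k.end - k.start, g.end - g.start)
            if ov / shorter > p.overlap_resolve_frac:
                clash = True
                break
        (dropped if clash else kept).append(g)
    kept.sort(key=lambda g: (g.start, g.end))
    return kept, dropped


# ------------------------------------------------------------- lncRNAs


def _islands(mask: np.ndarray, min_len: int) -> list[tuple[int, int]]:
    padded = np.concatenate([[False], mask, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return [(int(s), int(e)) for s, e in zip(starts, ends) if e - s >= min_len]


def call_lncrnas(
    evidence: EvidenceBundle,
    retained_genes: Sequence[GeneModel],
    params: Optional[AnnotationParams] = None,
    genome_id: str | None = None,
) -> list[GeneModel]:
    """Contiguous transcribed islands not explained by a same-strand retained
    CDS (with UTR slack). Antisense overlap with a CDS is allowed and
    flagged ``antisense=1``."""
    p = params or AnnotationParams()
    gid = genome_id or evidence.genome_id
    out: list[GeneModel] = []
    n_lnc = 0
    for strand in "+-":
        cov = evidence.coverage(strand)
        same = [g for g in retained_genes if g.strand == strand and g.kind == "CDS"]
        anti = [g for g in retained_genes if g.strand != strand and g.kind == "CDS"]

        def explained_span(g: GeneModel) -> tuple[int, int]:
            # assigned UTRs give the true transcribed unit; fall back to a
            # fixed slack when UTRs were not assigned
            bounds = [g.start, g.end]
            for utr in (g.utr5, g.utr3):
                if utr is not None:
                    bounds.extend(utr)
            if g.utr5 is None and g.utr3 is None:
                return max(g.start - p.utr_slack, 0), g.end + p.utr_slack
            return max(min(bounds) - 50, 0), max(bounds) + 50

        explained = merge_intervals([explained_span(g) for g in same])
        for s, e in _islands(cov >= p.cov_min, p.lncrna_min_len):
            ov = sum(max(0, min(e, ge) - max(s, gs)) for gs, ge in explained)
            if ov / (e - s) > 0.2:
                continue
            is_anti = any(min(e, g.end) - max(s, g.start) > 0 for g in anti)
            n_lnc += 1
            out.append(GeneModel(
                id=f"{gid}_ncRNA_{n_lnc:04d}_{strand}", genome_id=gid,
                start=s, end=e, strand=strand, kind="lncRNA",
                evidence={"transcript"},
                attributes={"antisense": int(is_anti)},
            ))
    out.sort(key=lambda g: (g.start, g.end, g.strand))
    for i, g in enumerate(out, 1):
        g.id = f"{gid}_ncRNA_{i:04d}"
    return out


# --------------------------------------------------- introns and UTRs


def assign_introns_utrs(
    genes: Sequence[GeneModel],
    junctions: Sequence[tuple[int, int, str, int]],
    evidence: EvidenceBundle,
    params: Optional[AnnotationParams] = None,
) -> list[GeneModel]:
    """Split exons at supported junctions and extend UTRs to the coverage
    boundary of the transcribed unit.

    A junction is accepted for a gene when it has >= j_min reads, matches the
    gene strand, and both ends fall within the gene span (+/- the UTR
    window); junctions that would break the spliced-length-divisible-by-3
    invariant of a CDS are rejected.
    """
    p = params or AnnotationParams()
    out: list[GeneModel] = []
    for g in genes:
        exons = list(g.exons)
        if g.kind == "CDS":
            for d, a, strand, reads in junctions:
                if strand != g.strand or reads < p.j_min:
                    continue
                if not (g.start - p.utr_slack <= d and a <= g.end + p.utr_slack):
                    continue
                new_exons = []
                applied = False
                for (s, e) in exons:
                    if s < d and a < e:
                        new_exons.extend([(s, d), (a, e)])
                        applied = True
                    else:
                        new_exons.append((s, e))
                if applied:
                    if sum(e - s for s, e in new_exons) % 3 == 0:
                        exons = sorted(new_exons)
        cov = evidence.coverage(g.strand)
        left = g.start
        while left > 0 and g.start - left < p.utr_max and cov[left - 1] >= p.cov_min:
            left -= 1
        right = g.end
        while right < len(cov) and right - g.end < p.utr_max and cov[right] >= p.cov_min:
            right += 1
        utr_left = (left, g.start) if left < g.start else None
        utr_right = (g.end, right) if right > g.end else None
        if g.strand == "+":
            utr5, utr3 = utr_left, utr_right
        else:
            utr5, utr3 = utr_right, utr_left
        out.append(GeneModel(
            id=g.id, genome_id=g.genome_id, start=g.start, end=g.end,
            strand=g.strand, kind=g.kind, exons=exons, utr5=utr5, utr3=utr3,
            evidence=set(g.evidence), category=g.category,
            attributes=dict(g.attributes),
        ))
    return out


# ------------------------------------------------------------------ CAI


@dataclass
class CodonUsageTable:
    """Relative adaptiveness w per sense codon: w = count / max count among
    the codons of the same amino acid; zero counts floored at 0.01."""

    w: dict[str, float]
    reference: str = ""

    @classmethod
    def from_counts(cls, counts: Mapping[str, int], reference: str = "") -> "CodonUsageTable":
        by_aa: dict[str, list[str]] = {}
        for codon in SENSE_CODONS:
            by_aa.setdefault(_CODON_TABLE[codon], []).append(codon)
        w: dict[str, float] = {}
        for aa, codons in by_aa.items():
            mx = max(counts.get(c, 0) for c in codons)
            for c in codons:
                w[c] = max(counts.get(c, 0) / mx, 0.01) if mx > 0 else 1.0
        return cls(w=w, reference=reference)

    @classmethod
    def from_table(cls, df: pd.DataFrame, reference: str = "") -> "CodonUsageTable":
        return cls.from_counts(dict(zip(df["codon"], df["count"])), reference)


def compute_cai(cds: str, table: CodonUsageTable) -> float:
    """Geometric mean of codon relative adaptiveness over all codons,
    excluding stops; Met and Trp enter with w = 1 by construction."""
    if len(cds) == 0:
        raise ValueError("zero-length CDS")
    if len(cds) % 3 != 0:
        raise ValueError("CDS length not divisible by 3")
    logs = []
    for i in range(0, len(cds), 3):
        codon = cds[i:i + 3]
        if codon in STOP_CODONS:
            if i != len(cds) - 3:
                raise ValueError("internal stop codon")
            continue
        wv = table.w.get(codon)
        if wv is None:  # ambiguous codon (N): skip
            continue
        logs.append(math.log(wv))
    if not logs:
        raise ValueError("no scorable codons")
    return math.exp(sum(logs) / len(logs))


# ------------------------------------------------------- genome fractions


def genome_fraction_stats(
    genes: Sequence[GeneModel], genome: Genome
) -> tuple[float, float]:
    """(fraction_transcribed, fraction_translated).

    Transcribed: union of gene spans, UTRs, and lncRNAs. Translated: union
    of CDS exon bases. Invariant: translated <= transcribed."""
    transcribed: list[tuple[int, int]] = []
    translated: list[tuple[int, int]] = []
    for g in genes:
        transcribed.append((g.start, g.end))
        for utr in (g.utr5, g.utr3):
            if utr is not None:
                transcribed.append(utr)
        if g.kind == "CDS":
            translated.extend(g.exons)
    glen = len(genome)
    return union_length(transcribed) / glen, union_length(translated) / glen


# ------------------------------------------------------------- pipeline


def annotate_genome(
    genome: Genome,
    evidence: EvidenceBundle,
    homology_hits: Optional[pd.DataFrame] = None,
    params: Optional[AnnotationParams] = None,
) -> tuple[list[GeneModel], AnnotationReport]:
    """Full stringent annotation of one genome: ORF calling, evidence
    filtering, intron/UTR assignment, lncRNA calling, fraction stats."""
    p = params or AnnotationParams()
    orfs = call_orfs(genome, p.min_orf_len)
    retained, report = integrate_evidence(orfs, genome, evidence,
                                          homology_hits, p)
    retained = assign_introns_utrs(retained, evidence.junctions, evidence, p)
    lncrnas = call_lncrnas(evidence, retained, p)
    genes = retained + lncrnas
    report.n_lncrna = len(lncrnas)
    report.fraction_transcribed, report.fraction_translated = \
        genome_fraction_stats(genes, genome)
    spliced = [g for g in retained if g.n_introns > 0]
    report.n_genes_with_introns = len(spliced)
    report.intron_fraction = len(spliced) / len(retained) if retained else 0.0
    report.mean_introns_per_spliced_gene = (
        float(np.mean([g.n_introns for g in spliced])) if spliced else 0.0
    )
    return genes, report
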
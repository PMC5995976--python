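"""Core domain objects shared by every analysis stage.

Coordinates are 0-based half-open on the forward strand of the genome;
minus-strand genes are stored in genomic orientation and reverse-complemented
only when their coding sequence is extracted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

DNA_ALPHABET = set("ACGTN")
STOP_CODONS = {"TAA", "TAG", "TGA"}

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

SENSE_CODONS = sorted(c for c, aa in _CODON_TABLE.items() if aa != "*")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(cds: str, trim_stop: bool = True) -> str:
    """Translate an in-frame coding sequence (standard code)."""
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    aa = "".join(_CODON_TABLE.get(cds[i:i + 3], "X") for i in range(0, len(cds), 3))
    if trim_stop and aa.endswith("*"):
        aa = aa[:-1]
    return aa


def codon_of(seq: str, i: int) -> str:
    return seq[3 * i:3 * i + 3]


def gc_content(seq: str) -> float:
    if not seq:
        return float("nan")
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    gc = np.count_nonzero((arr == ord("G")) | (arr == ord("C")))
    return gc / len(seq)


class FormatError(ValueError):
    """Raised for malformed external files."""


class ValidationError(ValueError):
    """Raised when parsed records violate model invariants."""


@dataclass
class Genome:
    id: str
    sequence: str
    strain_name: str = ""
    topology: str = "linear"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"genome {self.id}: empty sequence")
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise FormatError(f"genome {self.id}: illegal characters {sorted(bad)}")
        if not self.strain_name:
            self.strain_name = self.id

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def gc(self) -> float:
        return gc_content(self.sequence)


@dataclass
class GeneModel:
    """A located, stranded, possibly intron-containing gene."""

    id: str
    genome_id: str
    start: int
    end: int
    strand: str
    kind: str = "CDS"  # CDS | lncRNA | tRNA
    exons: list[tuple[int, int]] = field(default_factory=list)
    utr5: Optional[tuple[int, int]] = None
    utr3: Optional[tuple[int, int]] = None
    evidence: set[str] = field(default_factory=set)
    category: str = "unassigned"
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.exons:
            self.exons = [(self.start, self.end)]
        self.exons = sorted(tuple(e) for e in self.exons)
        self.validate()

    def validate(self) -> None:
        if self.strand not in "+-":
            raise ValidationError(f"{self.id}: bad strand {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValidationError(f"{self.id}: bad interval [{self.start},{self.end})")
        prev_end = None
        for (s, e) in self.exons:
            if s < self.start or e > self.end or s >= e:
                raise ValidationError(f"{self.id}: exon ({s},{e}) outside gene span")
            if prev_end is not None and s < prev_end:
                raise ValidationError(f"{self.id}: overlapping exons")
            prev_end = e
        if self.kind == "CDS" and self.spliced_length % 3 != 0:
            raise ValidationError(
                f"{self.id}: spliced CDS length {self.spliced_length} not divisible by 3"
            )

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    def coding_sequence(self, genome: "Genome | str") -> str:
        """Spliced coding-orientation sequence (reverse-complemented on -)."""
        seq = genome.sequence if isinstance(genome, Genome) else genome
        spliced = "".join(seq[s:e] for s, e in self.exons)
        return revcomp(spliced) if self.strand == "-" else spliced

    def protein(self, genome: "Genome | str") -> str:
        return translate(self.coding_sequence(genome))


@dataclass
class EvidenceBundle:
    """Per-strain experimental evidence used by the stringent annotation.

    coverage_plus/minus are dense per-base read-depth vectors; junctions are
    (donor, acceptor, strand, read_count) with donor < acceptor, 0-based
    half-open (intron = [donor, acceptor)); peptides are
    (protein_id, peptide_seq, spectra_count).
    """

    genome_id: str
    coverage_plus: np.ndarray
    coverage_minus: np.ndarray
    junctions: list[tuple[int, int, str, int]] = field(default_factory=list)
    peptides: list[tuple[str, str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.coverage_plus) != len(self.coverage_minus):
            raise ValidationError("strand coverage vectors differ in length")
        for d, a, s, _ in self.junctions:
            if not d < a:
                raise ValidationError(f"junction donor {d} >= acceptor {a}")
            if s not in "+-":
                raise ValidationError(f"junction strand {s!r}")

    def coverage(self, strand: str) -> np.ndarray:
        if strand == "+":
            return self.coverage_plus
        if strand == "-":
            return self.coverage_minus
        raise ValidationError("strandedness required: strand must be '+' or '-'")


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals, sorted and merged."""
    out: list[list[int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def union_length(intervals: list[tuple[int, int]]) -> int:
    return sum(e - s for s, e in merge_intervals(intervals))
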
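"""Readers and writers for the external formats used across the pipeline.

FASTA goes through Biopython; GFF3 uses the narrow dialect emitted by this
package (gene/mRNA/exon/CDS/ncRNA/tRNA rows, `##gff-version 3` header);
BEDGraph is one file per strand. Internal coordinates are 0-based half-open;
GFF3 and BEDGraph on disk follow their standard conventions (GFF3 1-based
inclusive, BEDGraph 0-based half-open).
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import (
    EvidenceBundle,
    FormatError,
    GeneModel,
    Genome,
    ValidationError,
)

# ---------------------------------------------------------------- FASTA


def read_fasta(path: str) -> list[Genome]:
    records = list(SeqIO.parse(path, "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    genomes = []
    for rec in records:
        seq = str(rec.seq).upper()
        genomes.append(Genome(id=rec.id, sequence=seq))
    return genomes


def write_fasta(genomes: Iterable[Genome], path: str, width: int = 80) -> None:
    records = [SeqRecord(Seq(g.sequence), id=g.id, description="") for g in genomes]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_protein_fasta(path: str) -> dict[str, str]:
    records = list(SeqIO.parse(path, "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    return {rec.id: str(rec.seq).upper() for rec in records}


def write_protein_fasta(proteins: dict[str, str], path: str) -> None:
    with open(path, "w") as fh:
        for pid in sorted(proteins):
            fh.write(f">{pid}\n{proteins[pid]}\n")


# ---------------------------------------------------------------- GFF3

_KIND_TO_FEATURE = {"CDS": "gene", "lncRNA": "ncRNA", "tRNA": "tRNA"}


def _fmt_attrs(pairs: list[tuple[str, str]]) -> str:
    return ";".join(f"{k}={v}" for k, v in pairs)


def _parse_attrs(text: str) -> dict[str, str]:
    out = {}
    for field in text.strip().split(";"):
        if field and "=" in field:
            k, v = field.split("=", 1)
            out[k] = v
    return out


def write_gff3(genes: Sequence[GeneModel], path: str) -> None:
    """Emit 1-based inclusive GFF3 (internal [s,e) -> columns s+1, e)."""
    lines = ["##gff-version 3"]
    for g in sorted(genes, key=lambda x: (x.genome_id, x.start, x.id)):
        attrs: list[tuple[str, str]] = [("ID", g.id)]
        if g.evidence:
            attrs.append(("evidence", ",".join(sorted(g.evidence))))
        if g.category != "unassigned":
            attrs.append(("category", g.category))
        for k, v in sorted(g.attributes.items()):
            attrs.append((k, str(v)))
        feat = _KIND_TO_FEATURE[g.kind]
        lines.append(
            "\t".join(
                [g.genome_id, "pandorapan", feat, str(g.start + 1), str(g.end),
                 ".", g.strand, ".", _fmt_attrs(attrs)]
            )
        )
        if g.kind == "CDS":
            for s, e in g.exons:
                lines.append(
                    "\t".join(
                        [g.genome_id, "pandorapan", "CDS", str(s + 1), str(e),
                         ".", g.strand, "0", _fmt_attrs([("Parent", g.id)])]
                    )
                )
            for utr, feat_name in ((g.utr5, "five_prime_UTR"), (g.utr3, "three_prime_UTR")):
                if utr is not None:
                    lines.append(
                        "\t".join(
                            [g.genome_id, "pandorapan", feat_name, str(utr[0] + 1),
                             str(utr[1]), ".", g.strand, ".",
                             _fmt_attrs([("Parent", g.id)])]
                        )
                    )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


_FEATURE_TO_KIND = {"gene": "CDS", "ncRNA": "lncRNA", "tRNA": "tRNA"}


def read_gff3(path: str, genomes: Sequence[Genome] | None = None) -> list[GeneModel]:
    """Parse the GFF3 dialect written by :func:`write_gff3`.

    Coordinate conversion is exact: internal_start = gff_start - 1,
    internal_end = gff_end. Validation errors list every offending gene id.
    """
    genome_len = {g.id: len(g) for g in genomes} if genomes else None
    parents: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}: expected 9 columns, got {len(cols)}")
            seqid, _, feat, start, end, _, strand, _, attr_text = cols
            s, e = int(start) - 1, int(end)
            attrs = _parse_attrs(attr_text)
            if feat in _FEATURE_TO_KIND:
                gid = attrs["ID"]
                parents[gid] = {
                    "id": gid, "genome_id": seqid, "start": s, "end": e,
                    "strand": strand, "kind": _FEATURE_TO_KIND[feat],
                    "exons": [], "utr5": None, "utr3": None,
                    "evidence": set(attrs.get("evidence", "").split(","))
                    if attrs.get("evidence") else set(),
                    "category": attrs.get("category", "unassigned"),
                    "attributes": {
                        k: v for k, v in attrs.items()
                        if k not in {"ID", "evidence", "category"}
                    },
                }
                order.append(gid)
            elif feat == "CDS":
                parents[attrs["Parent"]]["exons"].append((s, e))
            elif feat == "five_prime_UTR":
                parents[attrs["Parent"]]["utr5"] = (s, e)
            elif feat == "three_prime_UTR":
                parents[attrs["Parent"]]["utr3"] = (s, e)
    genes, problems = [], []
    for gid in order:
        spec = parents[gid]
        if genome_len is not None:
            glen = genome_len.get(spec["genome_id"])
            if glen is not None and spec["end"] > glen:
                problems.append(f"{gid}: gene end {spec['end']} beyond genome")
                continue
        try:
            genes.append(GeneModel(**spec))
        except ValidationError as exc:
            problems.append(str(exc))
    if problems:
        raise ValidationError("invalid gene models: " + "; ".join(problems))
    return genes


# ---------------------------------------------------------------- BEDGraph


def _read_bedgraph(path: str, genome: Genome) -> np.ndarray:
    cov = np.zeros(len(genome), dtype=float)
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            chrom, start, end, value = line.split("\t")
            if chrom != genome.id:
                continue
            s, e = int(start), int(end)
            if s < 0 or e > len(genome) or s >= e:
                raise FormatError(f"{path}: interval [{s},{e}) outside genome")
            cov[s:e] += float(value)  # overlapping intervals sum
    return cov


def read_bedgraph_stranded(
    path_plus: str, path_minus: str, genome: Genome
) -> tuple[np.ndarray, np.ndarray]:
    return _read_bedgraph(path_plus, genome), _read_bedgraph(path_minus, genome)


def write_bedgraph(coverage: np.ndarray, genome_id: str, path: str) -> None:
    """Run-length encode a dense per-base vector; zero runs are omitted."""
    with open(path, "w") as fh:
        if len(coverage) == 0:
            return
        change = np.flatnonzero(np.diff(coverage)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [len(coverage)]])
        for s, e in zip(starts, ends):
            v = coverage[s]
            if v != 0:
                fh.write(f"{genome_id}\t{s}\t{e}\t{v:.17g}\n")


# ---------------------------------------------------------------- TSV tables


def read_junctions(path: str) -> list[tuple[int, int, str, int]]:
    df = pd.read_csv(path, sep="\t")
    return [
        (int(r.donor), int(r.acceptor), str(r.strand), int(r.read_count))
        for r in df.itertuples()
    ]


def write_junctions(junctions: list[tuple[int, int, str, int]], path: str) -> None:
    pd.DataFrame(junctions, columns=["donor", "acceptor", "strand", "read_count"]).to_csv(
        path, sep="\t", index=False
    )


def read_peptides(path: str) -> list[tuple[str, str, int]]:
    df = pd.read_csv(path, sep="\t")
    return [
        (str(r.protein_id), str(r.peptide_seq), int(r.spectra_count))
        for r in df.itertuples()
    ]


def write_peptides(peptides: list[tuple[str, str, int]], path: str) -> None:
    pd.DataFrame(peptides, columns=["protein_id", "peptide_seq", "spectra_count"]).to_csv(
        path, sep="\t", index=False
    )


def read_evidence_bundle(
    genome: Genome, cov_plus: str, cov_minus: str,
    junctions: str | None = None, peptides: str | None = None,
) -> EvidenceBundle:
    plus, minus = read_bedgraph_stranded(cov_plus, cov_minus, genome)
    return EvidenceBundle(
        genome_id=genome.id,
        coverage_plus=plus,
        coverage_minus=minus,
        junctions=read_junctions(junctions) if junctions else [],
        peptides=read_peptides(peptides) if peptides else [],
    )


def read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str) -> None:
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
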
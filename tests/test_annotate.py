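"""Stringent annotation: ORF calling, evidence filtering, lncRNAs, introns,
CAI, and genome-fraction statistics."""

import math

import numpy as np
import pandas as pd
import pytest

from pandorapan.annotate import (
    AnnotationParams,
    CodonUsageTable,
    annotate_genome,
    assign_introns_utrs,
    call_lncrnas,
    call_orfs,
    compute_cai,
    genome_fraction_stats,
    integrate_evidence,
)
from pandorapan.models import EvidenceBundle, GeneModel, Genome, revcomp


def _genome(seq: str, gid: str = "g") -> Genome:
    return Genome(id=gid, sequence=seq)


def _evidence(genome: Genome, plus=None, minus=None, junctions=(), peptides=()):
    return EvidenceBundle(
        genome_id=genome.id,
        coverage_plus=plus if plus is not None else np.zeros(len(genome)),
        coverage_minus=minus if minus is not None else np.zeros(len(genome)),
        junctions=list(junctions),
        peptides=list(peptides),
    )


class TestCallOrfs:
    def test_simple_orf_and_strand_convention(self):
        orf_seq = "ATG" + "AAA" * 20 + "TAA"          # 66 nt
        pad = "C" * 30
        genome = _genome(pad + orf_seq + pad)
        fwd = call_orfs(genome, 60)
        assert any(g.start == 30 and g.end == 30 + 66 and g.strand == "+"
                   for g in fwd)
        # the same ORF on the reverse strand keeps genomic coordinates
        genome_rc = _genome(revcomp(pad + orf_seq + pad))
        rev = call_orfs(genome_rc, 60)
        glen = len(genome_rc)
        assert any(g.strand == "-" and g.start == glen - 96 and g.end == glen - 30
                   for g in rev)

    def test_nested_same_frame_resolved_to_longest(self):
        # two in-frame ATGs, one stop: a single ORF from the first ATG
        seq = "ATG" + "AAA" * 5 + "ATG" + "AAA" * 14 + "TAA"
        genome = _genome("C" * 12 + seq + "C" * 12)
        orfs = call_orfs(genome, 60)
        starts = [g.start for g in orfs if g.strand == "+"]
        assert starts == [12]

    def test_orf_with_n_excluded(self):
        seq = "ATG" + "AAA" * 10 + "AAN" + "AAA" * 10 + "TAA"
        genome = _genome("C" * 9 + seq + "C" * 9)
        assert all("N" not in genome.sequence[g.start:g.end]
                   for g in call_orfs(genome, 60))

    def test_min_len_validation(self):
        with pytest.raises(ValueError):
            call_orfs(_genome("ATGAAATAA" * 20), 9)

    def test_gc_rich_overpredicts_long_orfs(self):
        """Random GC-rich sequence yields more ORFs >= 300 nt than AT-rich
        sequence of the same length (stops are AT-rich codons)."""
        rng = np.random.default_rng(11)

        def random_genome(gc: float, n: int = 100_000) -> Genome:
            p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
            seq = "".join(rng.choice(list("ACGT"), size=n, p=p))
            return _genome(seq)

        high = np.mean([len(call_orfs(random_genome(0.62), 300)) for _ in range(3)])
        low = np.mean([len(call_orfs(random_genome(0.30), 300)) for _ in range(3)])
        assert high > 5 * max(low, 0.5)


class TestIntegrateEvidence:
    def test_no_evidence_discarded_with_reason(self):
        orf_seq = "ATG" + "GCT" * 40 + "TAA"
        genome = _genome("C" * 10 + orf_seq + "C" * 10)
        orfs = call_orfs(genome, 120)
        retained, report = integrate_evidence(orfs, genome, _evidence(genome))
        assert retained == []
        assert report.discard_reasons["no_evidence"] == len(orfs)

    def test_coverage_retains_and_flags(self):
        orf_seq = "ATG" + "GCT" * 40 + "TAA"
        genome = _genome("C" * 10 + orf_seq + "C" * 10)
        cov = np.zeros(len(genome))
        cov[5:135] = 10.0
        ev = _evidence(genome, plus=cov)
        retained, report = integrate_evidence(call_orfs(genome, 120), genome, ev)
        assert len(retained) == 1
        assert "transcript" in retained[0].evidence

    def test_homology_rescue_excludes_self(self):
        orf_seq = "ATG" + "GCT" * 40 + "TAA"
        genome = _genome("C" * 10 + orf_seq + "C" * 10)
        orfs = call_orfs(genome, 120)
        qid = orfs[0].id
        self_hit = pd.DataFrame(
            [{"query_id": qid, "subject_id": "x", "subject_genome": genome.id,
              "evalue": 1e-30}]
        )
        retained, _ = integrate_evidence(orfs, genome, _evidence(genome), self_hit)
        assert retained == []
        cross_hit = pd.DataFrame(
            [{"query_id": qid, "subject_id": "y", "subject_genome": "other",
              "evalue": 1e-30}]
        )
        retained, _ = integrate_evidence(orfs, genome, _evidence(genome), cross_hit)
        assert [g.id for g in retained] == [qid]
        assert retained[0].evidence >= {"homology"}

    def test_strandless_coverage_rejected(self):
        genome = _genome("ACGT" * 30)
        ev = _evidence(genome)
        with pytest.raises(Exception, match="strand"):
            ev.coverage("*")


class TestLncRnas:
    def _setup(self):
        genome = _genome("G" * 1000)
        cds = GeneModel(id="cds1", genome_id="g", start=100, end=400, strand="+",
                        evidence={"transcript"})
        return genome, cds

    def test_antisense_island_called_and_flagged(self):
        genome, cds = self._setup()
        minus = np.zeros(1000)
        minus[150:390] = 8.0
        ev = _evidence(genome, minus=minus)
        lnc = call_lncrnas(ev, [cds])
        assert len(lnc) == 1
        assert lnc[0].strand == "-"
        assert lnc[0].attributes["antisense"] == 1

    def test_island_explained_by_same_strand_cds_suppressed(self):
        genome, cds = self._setup()
        plus = np.zeros(1000)
        plus[100:400] = 8.0
        ev = _evidence(genome, plus=plus)
        assert call_lncrnas(ev, [cds]) == []

    def test_intergenic_island_called(self):
        genome, cds = self._setup()
        plus = np.zeros(1000)
        plus[850:1000] = 6.0   # only 150 nt: below min_len
        plus[600:810] = 6.0    # 210 nt island far from the CDS + UTR slack
        ev = _evidence(genome, plus=plus)
        params = AnnotationParams(utr_slack=100)
        lnc = call_lncrnas(ev, [cds], params)
        assert [(g.start, g.end) for g in lnc] == [(600, 810)]
        assert lnc[0].attributes["antisense"] == 0


class TestIntronsUtrs:
    def test_no_junctions_single_exon_utr_from_coverage(self):
        genome = _genome("G" * 500)
        gene = GeneModel(id="g1", genome_id="g", start=100, end=250, strand="+",
                         evidence={"transcript"})
        cov = np.zeros(500)
        cov[80:300] = 9.0
        ev = _evidence(genome, plus=cov)
        out = assign_introns_utrs([gene], [], ev)[0]
        assert out.n_introns == 0
        assert out.utr5 == (80, 100)
        assert out.utr3 == (250, 300)

    def test_minus_strand_utr_orientation(self):
        genome = _genome("G" * 500)
        gene = GeneModel(id="g1", genome_id="g", start=100, end=250, strand="-",
                         evidence={"transcript"})
        cov = np.zeros(500)
        cov[80:300] = 9.0
        ev = _evidence(genome, minus=cov)
        out = assign_introns_utrs([gene], [], ev)[0]
        assert out.utr5 == (250, 300)
        assert out.utr3 == (80, 100)

    def test_junction_splits_exons_keeping_frame(self):
        genome = _genome("G" * 600)
        gene = GeneModel(id="g1", genome_id="g", start=100, end=400, strand="+",
                         evidence={"transcript"})
        ev = _evidence(genome)
        # 60-nt intron keeps spliced length divisible by 3 -> accepted
        out = assign_introns_utrs([gene], [(200, 260, "+", 10)], ev)[0]
        assert out.exons == [(100, 200), (260, 400)]
        assert out.spliced_length % 3 == 0
        # a 50-nt intron would break the frame -> rejected
        out2 = assign_introns_utrs([gene], [(200, 250, "+", 10)], ev)[0]
        assert out2.n_introns == 0

    def test_junction_support_threshold(self):
        genome = _genome("G" * 600)
        gene = GeneModel(id="g1", genome_id="g", start=100, end=400, strand="+",
                         evidence={"transcript"})
        ev = _evidence(genome)
        out = assign_introns_utrs([gene], [(200, 260, "+", 2)], ev)[0]
        assert out.n_introns == 0  # below j_min


class TestCai:
    def test_maximal_w_codons_give_one(self):
        table = CodonUsageTable.from_counts({"AAA": 100, "AAG": 50, "TTT": 80})
        assert compute_cai("AAATTT", table) == pytest.approx(1.0)

    def test_hand_geometric_mean(self):
        table = CodonUsageTable.from_counts({"AAA": 100, "AAG": 50})
        assert compute_cai("AAAAAG", table) == pytest.approx(math.sqrt(0.5))

    def test_concatenation_identity(self):
        table = CodonUsageTable.from_counts(
            {"AAA": 100, "AAG": 30, "GCT": 50, "GCC": 100, "TGG": 5}
        )
        parts = ["AAAGCT", "AAGGCCTGG", "GCTGCC"]
        whole = "".join(parts)
        logs = []
        for part in parts:
            logs.extend([math.log(compute_cai(part, table))] * (len(part) // 3))
        assert compute_cai(whole, table) == pytest.approx(math.exp(np.mean(logs)))

    def test_synonymous_recoding_to_equal_w_is_invariant(self):
        table = CodonUsageTable.from_counts({"GGA": 60, "GGT": 60, "AAA": 10})
        assert compute_cai("GGAAAA", table) == pytest.approx(
            compute_cai("GGTAAA", table)
        )

    def test_errors(self):
        table = CodonUsageTable.from_counts({"AAA": 1})
        with pytest.raises(ValueError):
            compute_cai("", table)
        with pytest.raises(ValueError):
            compute_cai("AAAA", table)
        with pytest.raises(ValueError):
            compute_cai("TAAAAA", table)  # internal stop


class TestGenomeFractions:
    def test_degenerate_cases(self):
        genome = _genome("A" * 300)
        assert genome_fraction_stats([], genome) == (0.0, 0.0)
        whole = GeneModel(id="g", genome_id="g", start=0, end=300, strand="+")
        assert genome_fraction_stats([whole], genome) == (1.0, 1.0)

    def test_ten_gene_toy_matches_bitmap_oracle(self):
        rng = np.random.default_rng(3)
        genome = _genome("A" * 3000)
        genes = []
        transcribed = np.zeros(3000, dtype=bool)
        translated = np.zeros(3000, dtype=bool)
        for i in range(10):
            s = int(rng.integers(0, 2700))
            ln = int(rng.integers(30, 100)) * 3
            e = min(s + ln, 3000)
            utr3 = (e, min(e + 50, 3000))
            g = GeneModel(id=f"g{i}", genome_id="g", start=s, end=e, strand="+",
                          utr3=utr3)
            genes.append(g)
            transcribed[s:e] = True
            transcribed[utr3[0]:utr3[1]] = True
            translated[s:e] = True
        ft, fl = genome_fraction_stats(genes, genome)
        assert ft == pytest.approx(transcribed.mean())
        assert fl == pytest.approx(translated.mean())


@pytest.fixture(scope="module")
def annotated(small_clade):
    s = "A1"
    genes, report = annotate_genome(
        small_clade.genomes[s], small_clade.evidence[s]
    )
    return s, genes, report


class TestOnSimulatedClade:
    """Annotation accuracy against the simulator's ground truth."""

    @staticmethod
    def _overlap(a, b):
        return max(0, min(a[1], b[1]) - max(a[0], b[0]))

    def test_recall_of_expressed_truth_genes(self, small_clade, annotated):
        s, genes, _ = annotated
        cds = [g for g in genes if g.kind == "CDS"]
        truth = small_clade.truth.genes
        elig = truth[(truth.genome_id == s) & truth.expressed
                     & (truth.end - truth.start >= 300)]
        hit = sum(
            1 for r in elig.itertuples()
            if any(g.strand == r.strand
                   and self._overlap((r.start, r.end), (g.start, g.end))
                   >= 0.5 * (r.end - r.start) for g in cds)
        )
        assert hit / len(elig) >= 0.95

    def test_spurious_orfs_discarded(self, small_clade, annotated):
        s, genes, report = annotated
        cds = [g for g in genes if g.kind == "CDS"]
        truth = small_clade.truth.genes[small_clade.truth.genes.genome_id == s]
        spans = [(r.start, r.end, r.strand) for r in truth.itertuples()]
        spurious_kept = sum(
            1 for g in cds
            if not any(st == g.strand
                       and self._overlap((a, b), (g.start, g.end))
                       >= 0.5 * (g.end - g.start) for a, b, st in spans)
        )
        n_spurious_called = report.n_ab_initio - len(truth)
        assert n_spurious_called > 0
        assert spurious_kept / n_spurious_called <= 0.10

    def test_lncrna_recall(self, small_clade):
        """Truth lncRNAs recovered with recall >= 0.9 at default
        thresholds, pooled over all strains."""
        tot = rec = 0
        for s in sorted(small_clade.genomes):
            genes, _ = annotate_genome(
                small_clade.genomes[s], small_clade.evidence[s]
            )
            lnc = [g for g in genes if g.kind == "lncRNA"]
            tl = small_clade.truth.lncrnas[
                small_clade.truth.lncrnas.genome_id == s
            ]
            for r in tl.itertuples():
                tot += 1
                rec += any(
                    g.strand == r.strand
                    and self._overlap((r.start, r.end), (g.start, g.end))
                    >= 0.5 * (r.end - r.start) for g in lnc
                )
        assert rec / tot >= 0.9

    def test_intron_positions_recovered(self, small_clade, annotated):
        s, genes, _ = annotated
        truth = small_clade.truth.genes
        spliced_truth = truth[(truth.genome_id == s) & truth.has_intron
                              & truth.expressed]
        cds = [g for g in genes if g.kind == "CDS" and g.n_introns > 0]
        truth_junctions = {
            (j[0], j[1]) for j in small_clade.evidence[s].junctions if j[3] >= 3
        }
        found = set()
        for g in cds:
            for (e1s, e1e), (e2s, _) in zip(g.exons, g.exons[1:]):
                found.add((e1e, e2s))
        assert len(spliced_truth) > 0
        assert truth_junctions <= found

    def test_report_invariants(self, annotated):
        _, _, report = annotated
        assert report.fraction_translated <= report.fraction_transcribed <= 1.0
        assert report.n_discarded == sum(report.discard_reasons.values())
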
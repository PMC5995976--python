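"""Gene-origin battery: positional context, composition gradient,
intergenic homology scan, disorder proxy, HGT tree rule."""

import numpy as np
import pandas as pd
import pytest

from pandorapan.denovo import (
    SubjectRegion,
    classify_hgt,
    compare_disorder,
    disorder_fraction,
    gradient_test,
    intergenic_scan,
    positional_filter,
    subject_regions_from_annotation,
)
from pandorapan.models import GeneModel, Genome
from pandorapan.simulate import sample_intergenic_orf


def _gene(i, category="core", genome="A"):
    return GeneModel(id=f"g{i}", genome_id=genome, start=i * 100,
                     end=i * 100 + 90, strand="+")


class TestPositionalFilter:
    def _setup(self, categories):
        genes = [_gene(i) for i in range(len(categories))]
        cats = {g.id: c for g, c in zip(genes, categories)}
        block = {g.id for g, c in zip(genes, categories)
                 if c in ("core", "clade_specific")}
        return genes, cats, block

    def test_interspersed_gene_passes(self):
        genes, cats, block = self._setup(
            ["core", "strain_specific", "clade_specific"])
        out = positional_filter(genes, cats, block)
        assert out.positional_context_ok.tolist() == [True]

    def test_terminal_gene_fails(self):
        genes, cats, block = self._setup(["strain_specific", "core", "core"])
        out = positional_filter(genes, cats, block)
        assert out.positional_context_ok.tolist() == [False]

    def test_flank_window_respected(self):
        layout = ["core", "strain_specific", "strain_specific", "core"]
        genes, cats, block = self._setup(layout)
        wide = positional_filter(genes, cats, block, max_flank=2)
        assert dict(zip(wide.gene_id, wide.positional_context_ok)) == \
            {"g1": True, "g2": True}
        narrow = positional_filter(genes, cats, block, max_flank=1)
        # each strain-specific gene now has a bare strain-specific neighbour
        # on one side, outside the 1-gene window of any block member
        assert dict(zip(narrow.gene_id, narrow.positional_context_ok)) == \
            {"g1": False, "g2": False}

    def test_non_block_neighbors_do_not_count(self):
        genes, cats, block = self._setup(
            ["core", "strain_specific", "clade_specific"])
        out = positional_filter(genes, cats, set())
        assert out.positional_context_ok.tolist() == [False]


class TestGradientTest:
    @staticmethod
    def _rows(category, gc, ln, cai, n, rng):
        return pd.DataFrame({
            "gene_id": [f"{category}{i}" for i in range(n)],
            "genome_id": "A",
            "category": category,
            "gc": rng.normal(gc, 0.01, n),
            "length_nt": rng.normal(ln, 20, n),
            "cai": rng.normal(cai, 0.02, n),
        })

    def test_constructed_gradient_detected(self):
        rng = np.random.default_rng(0)
        feats = pd.concat([
            self._rows("core", 0.64, 900, 0.8, 40, rng),
            self._rows("clade_specific", 0.61, 600, 0.7, 40, rng),
            self._rows("strain_specific", 0.58, 400, 0.6, 40, rng),
        ])
        ig = self._rows("intergenic", 0.55, 220, 0.5, 40, rng)
        out = gradient_test(feats, ig)
        assert (out.verdict == "gradient").all()
        assert (out.filter(like="q_").to_numpy() < 0.05).all()

    def test_single_distribution_no_gradient(self):
        rng = np.random.default_rng(1)
        frames = [self._rows(c, 0.6, 500, 0.6, 40, rng)
                  for c in ("core", "clade_specific", "strain_specific")]
        ig = self._rows("intergenic", 0.6, 500, 0.6, 40, rng)
        out = gradient_test(pd.concat(frames), ig)
        assert not (out.verdict == "gradient").any()
        assert (out.filter(like="q_").to_numpy() > 0.01).all()

    def test_reversed_construction_reported(self):
        rng = np.random.default_rng(2)
        feats = pd.concat([
            self._rows("core", 0.50, 900, 0.8, 40, rng),
            self._rows("clade_specific", 0.55, 600, 0.7, 40, rng),
            self._rows("strain_specific", 0.60, 400, 0.6, 40, rng),
        ])
        ig = self._rows("intergenic", 0.65, 220, 0.5, 40, rng)
        out = gradient_test(feats, ig).set_index("feature")
        assert out.loc["gc", "verdict"] == "reversed"
        assert out.loc["length_nt", "verdict"] == "gradient"

    def test_insufficient_category(self):
        rng = np.random.default_rng(3)
        feats = pd.concat([
            self._rows("core", 0.64, 900, 0.8, 40, rng),
            self._rows("clade_specific", 0.61, 600, 0.7, 2, rng),
            self._rows("strain_specific", 0.58, 400, 0.6, 40, rng),
        ])
        ig = self._rows("intergenic", 0.55, 220, 0.5, 40, rng)
        out = gradient_test(feats, ig)
        assert (out.verdict == "insufficient_n").all()

    def test_unit_invariance(self):
        """Scaling length from nt to codons leaves the verdict unchanged."""
        rng = np.random.default_rng(4)
        feats = pd.concat([
            self._rows("core", 0.64, 900, 0.8, 30, rng),
            self._rows("clade_specific", 0.61, 600, 0.7, 30, rng),
            self._rows("strain_specific", 0.58, 400, 0.6, 30, rng),
        ])
        ig = self._rows("intergenic", 0.55, 220, 0.5, 30, rng)
        v1 = gradient_test(feats, ig).set_index("feature").verdict
        feats2, ig2 = feats.copy(), ig.copy()
        feats2["length_nt"] /= 3.0
        ig2["length_nt"] /= 3.0
        v2 = gradient_test(feats2, ig2).set_index("feature").verdict
        assert (v1 == v2).all()


class TestIntergenicScan:
    @staticmethod
    def _degrade(orf: str, rng) -> str:
        """Mutate 8% of sites, break the start, and insert two stops."""
        seq = list(orf)
        for i in rng.choice(len(seq), size=len(seq) // 12, replace=False):
            seq[i] = rng.choice([b for b in "ACGT" if b != seq[i]])
        seq[:3] = "ATA"
        for frac in (0.3, 0.6):
            k = 3 * int(len(seq) // 3 * frac)
            seq[k:k + 3] = "TAA"
        return "".join(seq)

    def test_planted_match_recovered_at_homologous_location(self):
        rng = np.random.default_rng(9)
        query = sample_intergenic_orf(0.6, 450, rng=rng)
        flank = "".join(rng.choice(list("ACGT"), size=300))
        region_seq = flank + self._degrade(query, rng) + flank
        regions = [SubjectRegion("r1", "B", "intergenic", 1000,
                                 1000 + len(region_seq), region_seq)]
        hom = {"q1": {"B": (900, 2500)}}
        hits = intergenic_scan({"q1": query}, regions, hom)
        assert len(hits) == 1
        assert bool(hits.iloc[0].homologous_location)

    def test_non_homologous_location_flagged_false(self):
        rng = np.random.default_rng(10)
        query = sample_intergenic_orf(0.6, 450, rng=rng)
        region_seq = self._degrade(query, rng)
        regions = [SubjectRegion("r1", "B", "intergenic", 5000,
                                 5000 + len(region_seq), region_seq)]
        hom = {"q1": {"B": (100, 900)}}
        hits = intergenic_scan({"q1": query}, regions, hom)
        assert len(hits) == 1
        assert not bool(hits.iloc[0].homologous_location)

    def test_shuffled_negative_controls_specific(self):
        """Composition-matched shuffled queries must not hit random
        intergenic sequence (false-positive rate <= 1%)."""
        rng = np.random.default_rng(11)
        regions = []
        for i in range(10):
            seq = "".join(rng.choice(list("ACGT"), size=800,
                                     p=[0.2, 0.3, 0.3, 0.2]))
            regions.append(SubjectRegion(f"r{i}", "B", "intergenic",
                                         i * 1000, i * 1000 + 800, seq))
        queries = {}
        for i in range(10):
            orf = sample_intergenic_orf(0.6, 450, rng=rng)
            codons = [orf[j:j + 3] for j in range(3, len(orf) - 3, 3)]
            rng.shuffle(codons)
            queries[f"s{i}"] = "ATG" + "".join(codons) + "TAA"
        hits = intergenic_scan(queries, regions)
        assert len(hits) / (len(queries) * len(regions)) <= 0.01

    def test_query_own_genome_skipped(self):
        rng = np.random.default_rng(12)
        query = sample_intergenic_orf(0.6, 450, rng=rng)
        regions = [SubjectRegion("r1", "A", "intergenic", 0, len(query),
                                 self._degrade(query, rng))]
        hits = intergenic_scan({"q1": query}, regions,
                               query_genome_of={"q1": "A"})
        assert len(hits) == 0

    def test_subject_regions_exclude_cds(self):
        genome = Genome(id="B", sequence="G" * 1000)
        cds = GeneModel(id="c", genome_id="B", start=200, end=500, strand="+")
        lnc = GeneModel(id="nc", genome_id="B", start=600, end=850,
                        strand="-", kind="lncRNA")
        regions = subject_regions_from_annotation(genome, [cds, lnc])
        kinds = {(r.kind, r.start, r.end) for r in regions}
        assert ("intergenic", 0, 200) in kinds
        assert ("intergenic", 500, 1000) in kinds
        assert ("ncRNA", 600, 850) in kinds
        assert not any(r.kind == "intergenic" and r.start < 500 < r.end
                       for r in regions)


class TestDisorder:
    def test_extreme_compositions(self):
        assert disorder_fraction("E" * 80) == 1.0
        assert disorder_fraction("I" * 40 + "L" * 40) == 0.0

    def test_compare_orders_groups(self):
        rng = np.random.default_rng(6)
        charged = ["".join(rng.choice(list("EDKRSQN"), size=80))
                   for _ in range(20)]
        hydrophobic = ["".join(rng.choice(list("ILVAFMG"), size=80))
                       for _ in range(20)]
        m_orfan, m_non, p = compare_disorder(charged, hydrophobic)
        assert m_orfan > m_non
        assert p < 1e-4

    def test_short_protein_single_window(self):
        assert disorder_fraction("E" * 20) == 1.0
        with pytest.raises(ValueError):
            disorder_fraction("")


class TestClassifyHgt:
    FAM2 = {"f1": "family", "f2": "family"}

    def test_sister_to_outgroup_is_ancestral(self):
        labels = dict(self.FAM2, c1="cellular", c2="cellular")
        assert classify_hgt("((f1,f2),(c1,c2));", labels) == "ancestral"

    def test_deep_nesting_is_acquisition(self):
        labels = dict(self.FAM2, c1="cellular", c2="cellular", c3="cellular")
        assert classify_hgt("(c1,(c2,(c3,(f1,f2))));", labels) == \
            "acquired_by_family"

    def test_cellular_tip_inside_family_is_donation(self):
        labels = dict(self.FAM2, c1="cellular", o1="other_virus")
        assert classify_hgt("((f1,(c1,f2)),o1);", labels) == "donated_by_family"

    def test_tip_order_invariance(self):
        labels = dict(self.FAM2, c1="cellular", c2="cellular", c3="cellular")
        a = classify_hgt("(c1,(c2,(c3,(f1,f2))));", labels)
        b = classify_hgt("((((f2,f1),c3),c2),c1);", labels)
        assert a == b == "acquired_by_family"

    def test_rerooting_within_outgroup_invariance(self):
        labels = dict(self.FAM2, c1="cellular", c2="cellular")
        a = classify_hgt("((f1,f2),(c1,c2));", labels)
        b = classify_hgt("(c1,(c2,(f1,f2)));", labels)
        assert a == b == "ancestral"


def test_truth_denovo_insertions_pass_positional_filter(tiny_products):
    """De novo genes inserted inside conserved gene neighbourhoods pass the
    positional-context rule in at least 90% of cases."""
    from pandorapan.pangenome import categorize
    from pandorapan.synteny import pairwise_collinearity

    prod = tiny_products
    categorized = categorize(prod.membership, prod.clade.clade_map)
    cat_of = dict(zip(categorized.gene_id, categorized.category))
    _, all_blocks = pairwise_collinearity(prod.ortholog_groups, prod.cds_orders)
    block_members = {
        gid for blocks in all_blocks.values() for b in blocks
        for pair in b.pairs for gid in pair
    }
    frames = []
    for s in sorted(prod.annotated):
        ordered = sorted((g for g in prod.annotated[s] if g.kind == "CDS"),
                         key=lambda g: g.start)
        frames.append(positional_filter(ordered, cat_of, block_members))
    pos = pd.concat(frames, ignore_index=True)
    truth = prod.clade.truth.genes
    denovo_spans = {}
    for r in truth[truth.origin == "de_novo"].itertuples():
        denovo_spans.setdefault(r.genome_id, []).append(
            (r.start, r.end, r.strand)
        )
    flags = []
    for s in sorted(prod.annotated):
        by_id = {g.id: g for g in prod.annotated[s]}
        order = prod.cds_orders[s]
        rank = {gid: i for i, gid in enumerate(order)}
        for r in pos[pos.genome_id == s].itertuples():
            g = by_id[r.gene_id]
            # insertions at the unstable chromosome ends are expected to
            # fail the rule; only interior insertions are scored
            if rank[g.id] < 3 or rank[g.id] >= len(order) - 3:
                continue
            if any(st == g.strand and min(e, g.end) - max(a, g.start)
                   >= 0.5 * (e - a)
                   for a, e, st in denovo_spans.get(s, [])):
                flags.append(bool(r.positional_context_ok))
    assert len(flags) >= 5
    assert np.mean(flags) >= 0.9
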
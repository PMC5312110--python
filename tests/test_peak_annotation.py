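import numpy as np
import pytest

from dosereg.io_formats import GeneModel, Peak
from dosereg.motif_scan import pax9_consensus_pwm
from dosereg.peak_annotation import (CATEGORIES, annotate_peaks, categorize,
                                     category_distribution, peak_anchor)
from dosereg.synthetic_data import simulate_genome


def oracle_category(d, inside):
    """Scalar re-statement of the taxonomy predicates, evaluated in order."""
    if abs(d) < 1000:
        return "TSS"
    if -5000 <= d <= -1000:
        return "promoter"
    if d >= 1000 and inside:
        return "intragenic"
    if not inside and (-10000 <= d <= -5000 or 1000 <= d <= 10000):
        return "proximal"
    if not inside and 10000 < abs(d) <= 100000:
        return "distal"
    return "others"


class TestPeakAnchor:
    @pytest.mark.parametrize("peak,expected", [
        (Peak("c", 100, 200), 150),
        (Peak("c", 100, 200, summit_offset=10), 110),
        (Peak("c", 100, 201), 150),   # odd width: floor midpoint
        (Peak("c", 100, 203), 151),
    ])
    def test_summit_else_floor_midpoint(self, peak, expected):
        assert peak_anchor(peak) == expected


class TestCategorize:
    plus_gene = GeneModel("chr1", 1_000_000, 1_020_000, "+", "gp")

    @pytest.mark.parametrize("anchor_offset,expected", [
        (0, (0, "TSS")),
        (-3000, (-3000, "promoter")),
        (5000, (5000, "intragenic")),
        (-7500, (-7500, "proximal")),
        (50_000, (50_000, "distal")),
        (150_000, (150_000, "others")),
        (-150_000, (-150_000, "others")),
    ])
    def test_plus_strand_category_windows(self, anchor_offset, expected):
        assert categorize(self.plus_gene.tss + anchor_offset, self.plus_gene) == expected

    def test_minus_strand_mirrors_plus(self):
        minus = GeneModel("chr1", 980_001, 1_000_001, "-", "gm")  # TSS = 1_000_000
        assert minus.tss == 1_000_000
        for d in (-3000, -7500, 0, 5000, 50_000, 150_000):
            # upstream of a minus-strand gene lies to the right of the TSS
            assert categorize(minus.tss - d, minus)[1] == \
                categorize(self.plus_gene.tss + d, self.plus_gene)[1]
            assert categorize(minus.tss - d, minus)[0] == d

    def test_one_bp_sweep_matches_predicate_oracle(self):
        gene = GeneModel("chr1", 1_000_000, 1_020_000, "+", "g")
        offsets = np.arange(-200_000, 200_001, 13)  # fine-grained unit-level sweep
        for d in offsets:
            anchor = gene.tss + int(d)
            inside = gene.start <= anchor < gene.end
            got_d, got_cat = categorize(anchor, gene)
            assert got_d == d
            assert got_cat == oracle_category(int(d), inside)

    def test_boundaries_pinned(self):
        g = self.plus_gene
        tss = g.tss
        assert categorize(tss + 999, g)[1] == "TSS"
        assert categorize(tss - 999, g)[1] == "TSS"
        assert categorize(tss - 1000, g)[1] == "promoter"
        assert categorize(tss - 5000, g)[1] == "promoter"
        assert categorize(tss + 1000, g)[1] == "intragenic"  # inside gene
        assert categorize(tss - 5001, g)[1] == "proximal"
        assert categorize(tss - 10_000, g)[1] == "proximal"
        assert categorize(tss - 10_001, g)[1] == "distal"
        assert categorize(tss + 100_000, g)[1] == "distal"
        assert categorize(tss + 100_001, g)[1] == "others"


class TestAnnotatePeaks:
    def test_empty_gene_set_rejected(self):
        with pytest.raises(ValueError):
            annotate_peaks([Peak("c", 0, 10)], [])

    def test_planted_genome_annotates_perfectly(self):
        pwm = pax9_consensus_pwm()
        plan = {c: 5 for c in CATEGORIES}
        _, genes, peaks, truth = simulate_genome(30, None, pwm, plan, seed=11)
        anns = {a.peak_id: a for a in annotate_peaks(peaks, genes)}
        for row in truth.peaks.itertuples():
            assert anns[row.peak_id].category == row.category

    def test_matches_brute_force_all_gene_scan(self):
        rng = np.random.default_rng(12)
        genes = []
        pos = 50_000
        for i in range(40):
            pos += int(rng.integers(120_000, 400_000))
            strand = "+" if rng.random() < 0.5 else "-"
            length = int(rng.integers(2000, 60_000))
            if strand == "+":
                genes.append(GeneModel("chr1", pos, pos + length, "+", f"g{i:03d}"))
            else:
                genes.append(GeneModel("chr1", pos - length + 1, pos + 1, "-", f"g{i:03d}"))
        span = genes[-1].end + 150_000
        peaks = [Peak("chr1", s, s + 300, name=f"pk{j}")
                 for j, s in enumerate(rng.integers(0, span - 300, 1000))]
        anns = annotate_peaks(peaks, genes)

        def brute(peak):
            anchor = peak_anchor(peak)
            best = None
            for g in genes:
                d, cat = categorize(anchor, g)
                key = (abs(d), g.gene_id)
                if best is None or key < best[0]:
                    best = (key, g.gene_id, d, cat)
            return best[1], best[2], best[3]

        assert len(anns) == 1000
        for peak, a in zip(peaks, anns):
            gid, d, cat = brute(peak)
            assert (a.gene_id, a.signed_distance, a.category) == (gid, d, cat)

    def test_equidistant_tie_broken_lexicographically(self):
        genes = [GeneModel("chr1", 100_000, 120_000, "+", "gB"),
                 GeneModel("chr1", 180_001, 200_001, "-", "gA")]
        # both TSSs 50 kb from the anchor at 150,000
        peak = Peak("chr1", 149_850, 150_150)
        a = annotate_peaks([peak], genes)[0]
        assert a.gene_id == "gA"

    def test_strand_mirror_leaves_categories_unchanged(self):
        pwm = pax9_consensus_pwm()
        plan = {c: 3 for c in CATEGORIES}
        seqs, genes, peaks, _ = simulate_genome(18, None, pwm, plan, seed=13)
        L = len(next(iter(seqs.values())))
        flipped_genes = [GeneModel(g.chrom, L - g.end, L - g.start,
                                   "-" if g.strand == "+" else "+", g.gene_id)
                         for g in genes]
        flipped_peaks = [Peak(p.chrom, L - p.end, L - p.start,
                              summit_offset=(p.end - p.start - 1 - p.summit_offset
                                             if p.summit_offset is not None else None),
                              name=p.name)
                         for p in peaks]
        orig = {a.peak_id: a.category for a in annotate_peaks(peaks, genes)}
        mirr = {a.peak_id: a.category for a in annotate_peaks(flipped_peaks, flipped_genes)}
        assert orig == mirr


class TestCategoryDistribution:
    def test_all_tss_gives_unit_fraction(self):
        g = [GeneModel("chr1", 1000, 3000, "+", "g")]
        peaks = [Peak("chr1", 900, 1200, name=f"p{i}") for i in range(4)]
        dist = category_distribution(annotate_peaks(peaks, g)).set_index("category")
        assert dist.loc["TSS", "fraction"] == 1.0

    def test_uniform_plan_gives_uniform_fractions(self):
        plan = {c: 5 for c in CATEGORIES}
        _, genes, peaks, _ = simulate_genome(30, None, None, plan, seed=14)
        dist = category_distribution(annotate_peaks(peaks, genes))
        np.testing.assert_allclose(dist["fraction"], 1 / 6, atol=1e-12)
        assert dist["fraction"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            category_distribution([])
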
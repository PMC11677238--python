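"""Promoter windows, peak-to-gene assignment, binding matrix, coverage."""

import numpy as np
import pytest

from mitoreg import binding as bd
from mitoreg.genome_io import GeneRecord, GenomeAnnotation, GeneSet, Peak, PeakSet
from .conftest import make_peakset
from ._oracles import brute_force_assignment, window_for


class TestPromoterWindow:
    def test_plus_strand_definition(self):
        gene = GeneRecord("g", "chr1", "+", 5000, 9000)
        w = bd.promoter_window(gene, 2000, 2000)
        assert (w.lo, w.hi) == (3000, 7000)

    def test_clipped_at_chromosome_start(self):
        gene = GeneRecord("g", "chr1", "+", 500, 1500)
        w = bd.promoter_window(gene, 2000, 2000)
        assert (w.lo, w.hi) == (0, 2500)

    def test_minus_strand_is_mirror_of_plus(self):
        gene = GeneRecord("g", "chr1", "-", 2000, 5001)  # tss = 5000
        w = bd.promoter_window(gene, 2000, 2000)
        assert (w.lo, w.hi) == (3001, 7001)

    @pytest.mark.parametrize("strand", ["+", "-"])
    @pytest.mark.parametrize("w_up,w_down", [(2000, 2000), (2000, 0), (0, 500), (100, 1)])
    def test_window_contains_tss(self, strand, w_up, w_down):
        gene = GeneRecord("g", "chr1", strand, 5000, 9000)
        w = bd.promoter_window(gene, w_up, w_down)
        assert w.lo <= gene.tss < w.hi

    def test_gene_region_extends_upstream_only(self):
        plus = GeneRecord("g", "chr1", "+", 5000, 9000)
        w = bd.gene_region_window(plus, 2000)
        assert (w.lo, w.hi) == (3000, 9000)
        minus = GeneRecord("h", "chr1", "-", 5000, 9000)  # tss = 8999
        w = bd.gene_region_window(minus, 2000)
        assert (w.lo, w.hi) == (5000, 11000)


class TestAssignment:
    def test_overlapping_peak_assigned(self, small_annotation):
        ps = make_peakset("T", [("chr1", 4900, 5100)])  # gA promoter [3000, 7000)
        hits = bd.assign_peaks_to_genes(ps, small_annotation)
        assert hits == {"gA": [0]}

    def test_half_open_boundary_not_assigned(self, small_annotation):
        # gA window [3000, 7000): a peak ending exactly at 3000 does not touch it
        ps = make_peakset("T", [("chr1", 2990, 3000)])
        assert bd.assign_peaks_to_genes(ps, small_annotation) == {}
        # one base further does
        ps = make_peakset("T", [("chr1", 2990, 3001)])
        assert bd.assign_peaks_to_genes(ps, small_annotation) == {"gA": [0]}

    def test_peak_may_hit_multiple_genes(self):
        ann = GenomeAnnotation(
            [GeneRecord("g1", "chr1", "+", 5000, 6000), GeneRecord("g2", "chr1", "+", 7000, 8000)]
        )
        ps = make_peakset("T", [("chr1", 4800, 5200)])
        hits = bd.assign_peaks_to_genes(ps, ann)
        assert set(hits) == {"g1", "g2"}

    def test_unmatched_chromosome_warns(self, small_annotation):
        ps = make_peakset("T", [("chrX", 100, 200)])
        with pytest.warns(UserWarning, match="chrX"):
            assert bd.assign_peaks_to_genes(ps, small_annotation) == {}

    @pytest.mark.parametrize("mode", ["promoter", "gene_region"])
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_scan(self, seed, mode):
        """Tree-based assignment equals the quadratic all-pairs overlap scan."""
        rng = np.random.default_rng(seed)
        genes = []
        pos = {c: 1000 for c in ("chr1", "chr2")}
        for i in range(rng.integers(3, 40)):
            chrom = "chr1" if rng.random() < 0.5 else "chr2"
            start = pos[chrom] + int(rng.integers(0, 8000))
            end = start + int(rng.integers(200, 5000))
            pos[chrom] = end
            genes.append(GeneRecord(f"g{i}", chrom, "+" if rng.random() < 0.5 else "-", start, end))
        ann = GenomeAnnotation(genes)
        peaks = []
        for _ in range(int(rng.integers(1, 200))):
            chrom = "chr1" if rng.random() < 0.5 else "chr2"
            start = int(rng.integers(0, max(pos.values()) + 4000))
            peaks.append((chrom, start, start + int(rng.integers(50, 900))))
        ps = make_peakset("T", peaks)
        w_up, w_down = int(rng.integers(0, 3000)), int(rng.integers(1, 3000))
        got = bd.assign_peaks_to_genes(ps, ann, mode=mode, w_up=w_up, w_down=w_down)
        got_pairs = {(g, i) for g, idx in got.items() for i in idx}
        sorted_peaks = [(p.chrom, p.start, p.end) for p in ps.peaks]
        if mode == "promoter":
            oracle_genes = [(g.gene_id, g.chrom, g.strand, g.tss) for g in ann]
            expected = brute_force_assignment(sorted_peaks, oracle_genes, w_up, w_down)
        else:
            expected = set()
            for g in ann:
                lo, hi = (g.tss - w_up, g.end) if g.strand == "+" else (g.start, g.tss + w_up + 1)
                lo = max(lo, 0)
                for i, (c, s, e) in enumerate(sorted_peaks):
                    if c == g.chrom and s < hi and lo < e:
                        expected.add((g.gene_id, i))
        assert got_pairs == expected

    @pytest.mark.parametrize("seed", range(5))
    def test_strand_mirror_invariance(self, seed):
        """Reflecting all coordinates and flipping strands preserves hits."""
        rng = np.random.default_rng(100 + seed)
        L = 200_000
        genes, peaks = [], []
        pos = 1000
        for i in range(10):
            start = pos + int(rng.integers(0, 6000))
            end = start + int(rng.integers(300, 3000))
            pos = end
            genes.append(GeneRecord(f"g{i}", "chr1", "+" if rng.random() < 0.5 else "-", start, end))
        for _ in range(50):
            s = int(rng.integers(0, L - 1000))
            peaks.append(("chr1", s, s + int(rng.integers(50, 800))))
        ann = GenomeAnnotation(genes)
        ps = make_peakset("T", peaks)
        fwd = bd.assign_peaks_to_genes(ps, ann, w_up=1500, w_down=700)

        flip = {"+": "-", "-": "+"}
        mirrored_genes = [
            GeneRecord(g.gene_id, g.chrom, flip[g.strand], L - g.end, L - g.start) for g in genes
        ]
        mirrored_peaks = [(c, L - e, L - s) for c, s, e in peaks]
        m_ann = GenomeAnnotation(mirrored_genes)
        m_ps = make_peakset("T", mirrored_peaks)
        rev = bd.assign_peaks_to_genes(m_ps, m_ann, w_up=1500, w_down=700)
        assert set(fwd) == set(rev)


class TestBindingMatrix:
    def test_construction_and_cells(self):
        m = bd.build_binding_matrix(
            {"A": {"g1": [0], "g2": [1, 2]}, "B": {"g2": [0]}}, ["g1", "g2", "g3"]
        )
        assert m.bound.sum() == 3
        assert m.targets_of("A") == {"g1", "g2"}
        assert m.binders_of("g2") == {"A", "B"}
        assert not m.is_bound("B", "g3")

    def test_all_false_when_no_assignments(self):
        m = bd.build_binding_matrix({"A": {}, "B": {}}, ["g1", "g2"])
        assert not m.bound.any()

    def test_genes_outside_universe_dropped(self):
        m = bd.build_binding_matrix({"A": {"g1": [0], "zz": [1]}}, ["g1"])
        assert m.targets_of("A") == {"g1"}
        assert m.n_dropped_genes == 1

    def test_duplicate_tf_rejected(self):
        with pytest.raises(bd.ValidationError):
            bd.BindingMatrix(tf_names=["A", "A"], gene_ids=["g"], bound=np.zeros((2, 1), bool))

    @pytest.mark.parametrize("seed", range(5))
    def test_row_sums_equal_assignment_counts(self, seed):
        rng = np.random.default_rng(seed)
        universe = [f"g{i}" for i in range(30)]
        assignments = {
            f"T{k}": {g: [0] for g in rng.choice(universe, size=rng.integers(0, 20), replace=False)}
            for k in range(4)
        }
        m = bd.build_binding_matrix(assignments, universe)
        for k, tf in enumerate(m.tf_names):
            assert m.bound[k].sum() == len(assignments[tf])

    def test_round_trip_via_tsv(self, tmp_path):
        m = bd.build_binding_matrix({"A": {"g1": [0]}, "B": {"g2": [0]}}, ["g1", "g2"])
        path = tmp_path / "matrix.tsv"
        m.write(path)
        back = bd.BindingMatrix.read(path)
        assert back.tf_names == m.tf_names
        assert back.gene_ids == m.gene_ids
        assert (back.bound == m.bound).all()


class TestCoverage:
    def test_enumerated_example(self):
        m = bd.build_binding_matrix(
            {"A": {"t1": [0], "t2": [0], "t3": [0]}, "B": {"t1": [0]}},
            ["t1", "t2", "t3", "t4"],
        )
        report = bd.coverage_stats(m, GeneSet("targets", frozenset({"t1", "t2", "t3", "t4"})))
        assert report.n_bound_ge1 == 3
        assert report.fraction_bound_ge1 == pytest.approx(0.75)
        assert report.tfs_over_half == ["A"]  # 3 > 2; B binds 1, not > 2

    def test_all_false_matrix(self):
        m = bd.build_binding_matrix({"A": {}, "B": {}}, ["g1", "g2"])
        report = bd.coverage_stats(m, GeneSet("s", frozenset({"g1", "g2"})))
        assert report.n_bound_ge1 == 0 and report.tfs_over_half == []

    def test_over_half_is_strict(self):
        m = bd.build_binding_matrix({"A": {"g1": [0], "g2": [0]}}, ["g1", "g2", "g3", "g4"])
        report = bd.coverage_stats(m, GeneSet("s", frozenset({"g1", "g2", "g3", "g4"})))
        assert report.tfs_over_half == []  # 2 of 4 is not > half

    def test_union_equals_set_algebra(self):
        rng = np.random.default_rng(7)
        universe = [f"g{i}" for i in range(50)]
        assignments = {
            f"T{k}": {g: [0] for g in rng.choice(universe, size=15, replace=False)} for k in range(5)
        }
        m = bd.build_binding_matrix(assignments, universe)
        target = GeneSet("s", frozenset(rng.choice(universe, size=20, replace=False)))
        report = bd.coverage_stats(m, target)
        union = set().union(*(set(a) for a in assignments.values()))
        assert report.n_bound_ge1 == len(union & target.genes)

    def test_empty_intersection_is_error(self):
        m = bd.build_binding_matrix({"A": {}}, ["g1"])
        with pytest.raises(ValueError):
            bd.coverage_stats(m, GeneSet("s", frozenset({"zz"})))


class TestGenomicDistribution:
    def test_manual_classification(self, small_annotation):
        # gA: '+' 5000-8000, promoter [3000, 7000); gB: '-' 15000-18000, tss 17999
        peaks = [
            ("chr1", 4950, 5050),  # summit 5000 -> promoter of gA
            ("chr1", 7400, 7600),  # summit 7500 -> inside gA body, beyond promoter
            ("chr1", 11000, 11200),  # summit 11100 -> intergenic
            ("chr1", 16400, 16600),  # summit 16500 -> gB body (promoter starts 16000? [16000,20000) contains it)
        ]
        ps = make_peakset("T", peaks)
        dist = bd.genomic_distribution(ps, small_annotation)
        # gB '-' tss=17999, window [17999-2000+1, 17999+2000+1) = [16000, 20000): summit 16500 is promoter
        assert dist == pytest.approx({"promoter": 0.5, "gene_body": 0.25, "intergenic": 0.25})

    def test_fractions_sum_to_one(self, small_annotation):
        rng = np.random.default_rng(3)
        peaks = []
        for _ in range(40):
            s = int(rng.integers(0, 30000))
            peaks.append(("chr1", s, s + 200))
        dist = bd.genomic_distribution(make_peakset("T", peaks), small_annotation)
        assert sum(dist.values()) == pytest.approx(1.0)

    def test_priority_promoter_over_body(self):
        ann = GenomeAnnotation([GeneRecord("g", "chr1", "+", 5000, 20000)])
        ps = make_peakset("T", [("chr1", 5950, 6050)])  # summit 6000: in body AND promoter window
        dist = bd.genomic_distribution(ps, ann)
        assert dist["promoter"] == 1.0


class TestTSSProfile:
    def test_summit_at_tss_lands_in_zero_bin(self, small_annotation):
        ps = make_peakset("T", [("chr1", 4950, 5050)])  # summit 5000 = gA tss
        prof = bd.tss_profile(ps, small_annotation, flank=3000, bin=100)
        zero_bin = np.flatnonzero(prof.counts)
        assert list(prof.bin_edges[zero_bin]) == [0]
        assert prof.n_within_flank == 1

    def test_minus_strand_upstream_sign(self, small_annotation):
        # gB is '-' with tss 17999; 150 bp upstream means summit at 18149
        ps = make_peakset("T", [("chr1", 18100, 18199)])  # odd length -> summit 18149
        prof = bd.tss_profile(ps, small_annotation, flank=3000, bin=100)
        (bin_idx,) = np.flatnonzero(prof.counts)
        assert prof.bin_edges[bin_idx] == -200  # falls in [-200, -100)

    def test_far_peaks_counted_but_excluded(self, small_annotation):
        ps = make_peakset("T", [("chr1", 10900, 11100), ("chr1", 4950, 5050)])
        prof = bd.tss_profile(ps, small_annotation, flank=1000, bin=100)
        assert prof.n_total == 2
        assert prof.n_within_flank == prof.counts.sum() == 1

    def test_bin_must_divide_span(self, small_annotation):
        with pytest.raises(ValueError):
            bd.tss_profile(make_peakset("T", [("chr1", 0, 10)]), small_annotation, flank=1000, bin=300)
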
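"""Hash-seeded IBD detection: planted segments, nulls, masks, summaries."""

import numpy as np
import pytest

from isopop import (MarkerMap, PhasedPanel, germline_scan,
                    filter_segments_by_mask, pair_summaries,
                    sparse_region_mask, true_ibd_segments)
from isopop.segments import IBDSegment


def _regular_map(n, cm_per_marker=0.025, chrom="1"):
    pos = np.arange(n) * cm_per_marker
    return MarkerMap(
        np.array([chrom] * n, dtype=object),
        np.array([f"m{i}" for i in range(n)], dtype=object),
        np.maximum(1, (pos * 1e6).astype(np.int64)), pos)


def _random_panel(n_samples, n_markers, seed, freq=None,
                  cm_per_marker=0.025):
    rng = np.random.default_rng(seed)
    p = np.full(n_markers, 0.5) if freq is None else freq
    haps = (rng.random((2 * n_samples, n_markers)) < p).astype(np.uint8)
    return PhasedPanel(
        haps, np.array([f"s{i}" for i in range(n_samples)], dtype=object),
        _regular_map(n_markers, cm_per_marker))


class TestGermlineScan:
    def test_shared_full_haplotype_spans_chromosome(self):
        panel = _random_panel(2, 2000, seed=0)
        panel.haplotypes[2] = panel.haplotypes[0]  # s1 hap0 := s0 hap0
        segs = germline_scan(panel, min_cm=3.0)
        assert len(segs) == 1
        s = segs[0]
        assert (s.sample_a, s.sample_b) == ("s0", "s1")
        assert s.start_idx <= 5 and s.end_idx >= 1994

    def test_planted_tracts_recovered_with_tight_boundaries(self):
        """Planted 5-15 cM copies are found with boundary error <= 64
        markers, one detected segment per plant."""
        rng = np.random.default_rng(1)
        n_markers = 6000  # 150 cM at 0.025 cM spacing
        panel = _random_panel(12, n_markers, seed=2,
                              freq=rng.uniform(0.3, 0.7, n_markers))
        plants = []
        for k in range(5):
            a, b = 2 * k, 2 * k + 1  # samples
            start = 200 + 1100 * k
            length = int((5 + 2 * k) / 0.025)
            panel.haplotypes[2 * b, start:start + length] = \
                panel.haplotypes[2 * a, start:start + length]
            plants.append((f"s{a}", f"s{b}", start, start + length - 1))
        segs = germline_scan(panel, min_cm=3.0)
        for sa, sb, lo, hi in plants:
            match = [s for s in segs
                     if {s.sample_a, s.sample_b} == {sa, sb}]
            assert len(match) == 1
            s = match[0]
            assert abs(s.start_idx - lo) <= 64
            assert abs(s.end_idx - hi) <= 64

    def test_null_panel_yields_almost_no_false_ibd(self):
        """Unrelated random haplotypes: total falsely detected length
        under 1% of the scanned genome."""
        total = 0.0
        for seed in range(3):
            panel = _random_panel(20, 5000, seed=10 + seed)
            segs = germline_scan(panel, min_cm=3.0)
            total += sum(s.length_cm for s in segs)
        genome = 5000 * 0.025
        assert total / (3 * genome) < 0.01

    def test_detection_against_ground_truth(self, isolate_sim):
        """>= 95% of true segments >= 5 cM are hit by a detected segment
        covering >= 80% of their length."""
        panel, lab = isolate_sim
        segs = germline_scan(panel, min_cm=3.0)
        by_pair = {}
        for s in segs:
            by_pair.setdefault((s.sample_a, s.sample_b), []).append(s)
        ids = [str(x) for x in panel.sample_ids]
        n_true = n_hit = 0
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                truths = true_ibd_segments(lab, ids[i], ids[j], min_cm=5.0)
                if not truths:
                    continue
                found = by_pair.get((ids[i], ids[j]), [])
                for t in truths:
                    n_true += 1
                    cover = 0.0
                    for d in found:
                        if d.chrom != t.chrom:
                            continue
                        cover += max(0.0, min(d.end_cm, t.end_cm)
                                     - max(d.start_cm, t.start_cm))
                    if cover >= 0.8 * t.length_cm:
                        n_hit += 1
        assert n_true > 50
        assert n_hit / n_true >= 0.95

    def test_mismatch_budget_holds_on_reported_segments(self, isolate_sim):
        """Re-check every reported segment against the best haplotype
        pairing: mismatches stay within 1 per 64 markers (plus ends)."""
        panel, _ = isolate_sim
        segs = germline_scan(panel, min_cm=3.0)
        assert segs
        for s in segs:
            budget = max(1, int(np.ceil(s.n_markers / 64)))
            assert s.n_mismatch <= budget

    def test_invariant_to_sample_and_haplotype_order(self):
        panel = _random_panel(8, 3000, seed=3)
        # plant one tract
        panel.haplotypes[5, 1000:1500] = panel.haplotypes[0, 1000:1500]
        segs1 = germline_scan(panel, min_cm=3.0)
        # swap haplotypes within each sample and reverse sample order
        h = panel.haplotypes.copy()
        swapped = h.reshape(8, 2, -1)[::-1, ::-1].reshape(16, -1)
        panel2 = PhasedPanel(swapped, panel.sample_ids[::-1].copy(),
                             panel.markers, panel.populations[::-1].copy())
        segs2 = germline_scan(panel2, min_cm=3.0)
        key = [(s.sample_a, s.sample_b, s.start_idx, s.end_idx)
               for s in segs1]
        key2 = [(s.sample_a, s.sample_b, s.start_idx, s.end_idx)
                for s in segs2]
        assert sorted(key) == sorted(key2)

    def test_short_chromosome_skipped(self):
        panel = _random_panel(3, 40, seed=4)
        assert germline_scan(panel, min_cm=0.1) == []


class TestSparseMask:
    def test_uniform_density_empty(self):
        m = _regular_map(500, cm_per_marker=0.01)  # 10-kb spacing
        assert sparse_region_mask(m) == []

    def test_large_gap_masked(self):
        bp = np.concatenate([np.arange(1, 101) * 10_000,
                             2_000_000 + np.arange(100) * 10_000 + 1_000_000])
        m = MarkerMap(np.array(["1"] * 200, dtype=object),
                      np.array([f"m{i}" for i in range(200)], dtype=object),
                      bp, bp / 1e6)
        mask = sparse_region_mask(m)
        assert len(mask) == 1
        chrom, a, b = mask[0]
        assert a <= 1_000_000 and b >= 3_000_000

    def test_hand_trace_of_50_marker_rule(self):
        """49 dense markers, then a 1.5-Mb jump, then dense again: every
        50-marker window crossing the jump spans > 1 Mb."""
        bp = np.concatenate([np.arange(1, 50) * 1_000,
                             [49_000 + 1_500_000],
                             49_000 + 1_500_000 + np.arange(1, 60) * 1_000])
        m = MarkerMap(np.array(["1"] * 109, dtype=object),
                      np.array([f"m{i}" for i in range(109)], dtype=object),
                      bp, bp / 1e6)
        mask = sparse_region_mask(m)
        # the jump is inside the mask
        assert any(a <= 49_000 and b >= 1_549_000 for _, a, b in mask)


class TestMaskFilter:
    def _seg(self, start, end):
        return IBDSegment("a", "b", "1", start / 1e6, end / 1e6,
                          start_bp=start, end_bp=end)

    def test_empty_mask_is_identity(self):
        segs = [self._seg(100, 2000)]
        assert filter_segments_by_mask(segs, []) == segs

    def test_segment_inside_mask_removed(self):
        segs = [self._seg(1000, 2000)]
        assert filter_segments_by_mask(segs, [("1", 500, 2500)]) == []

    def test_19_vs_21_percent_overlap(self):
        seg = self._seg(1, 1000)  # length 1000 bp
        kept = filter_segments_by_mask([seg], [("1", 1, 190)])     # 19%
        assert kept == [seg]
        kept = filter_segments_by_mask([seg], [("1", 1, 210)])     # 21%
        assert kept == []


class TestPairSummaries:
    def test_no_segments_gives_zero_means(self):
        labels = np.array(["P", "P", "P"], dtype=object)
        s = pair_summaries([], ["a", "b", "c"], labels, "within", "P")
        assert s.n_pairs == 3
        assert s.stats.loc["mean", "total_mb"] == 0.0

    def test_hand_arithmetic(self):
        segs = [
            IBDSegment("a", "b", "1", 0.0, 3.0, start_bp=1,
                       end_bp=3_000_000),
            IBDSegment("a", "b", "2", 0.0, 5.0, start_bp=1,
                       end_bp=5_000_000),
        ]
        labels = np.array(["P", "P"], dtype=object)
        s = pair_summaries(segs, ["a", "b"], labels, "within", "P")
        row = s.per_pair.iloc[0]
        assert row.n_segments == 2
        assert row.total_mb == pytest.approx(8.0, abs=0.01)
        assert row.mean_mb == pytest.approx(4.0, abs=0.01)

    def test_between_scope_counts_cross_pairs_only(self):
        segs = [IBDSegment("a", "c", "1", 0.0, 4.0, start_bp=1,
                           end_bp=4_000_000)]
        ids = ["a", "b", "c", "d"]
        labels = np.array(["P", "P", "Q", "Q"], dtype=object)
        s = pair_summaries(segs, ids, labels, "between")
        assert s.n_pairs == 4
        assert s.n_segments == 1
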
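"""Peak validation layers: flanking, overlap, distances, EDS windows."""

import numpy as np
import pandas as pd
import pytest

from recwas.annotate import (AnnotationRegion, eds_window_counts,
                             expand_to_regions, nearest_feature_distance,
                             overlap_proportion)
from recwas.exceptions import DegenerateDataError
from recwas.genio import PeakRegion


class TestExpand:
    def test_snp_point_flanked(self):
        regions = expand_to_regions([("chr1", 5_000_000)], 1_000_000)
        assert (regions[0].start, regions[0].end) == (4_000_000, 6_000_001)

    def test_clamped_at_zero(self):
        regions = expand_to_regions([("chr1", 500)], 1_000_000)
        assert regions[0].start == 0

    def test_interval_flanked(self):
        regions = expand_to_regions([("chr2", 10_000, 20_000, "g")],
                                    100_000)
        assert (regions[0].start, regions[0].end) == (0, 120_000)

    def test_overlapping_regions_not_merged(self):
        regions = expand_to_regions([("chr1", 100), ("chr1", 150)], 1000)
        assert len(regions) == 2


def _peaks():
    return [PeakRegion("chr1", 100, 200, "p1"),
            PeakRegion("chr1", 1000, 1100, "p2"),
            PeakRegion("chr2", 50, 80, "p3")]


class TestOverlap:
    def test_hand_enumerated_fraction(self):
        regions = [AnnotationRegion("chr1", 150, 400, "r1"),
                   AnnotationRegion("chr2", 0, 60, "r2")]
        frac, flags = overlap_proportion(_peaks(), regions)
        assert frac == pytest.approx(2 / 3)
        assert flags.tolist() == [True, False, True]

    def test_half_open_abutment_is_not_a_hit(self):
        regions = [AnnotationRegion("chr1", 200, 300, "r")]
        frac, flags = overlap_proportion(_peaks(), regions)
        assert not flags[0]  # peak ends exactly where the region starts

    def test_fully_contained_peak_hits(self):
        regions = [AnnotationRegion("chr1", 0, 5000, "r")]
        _, flags = overlap_proportion(_peaks(), regions)
        assert flags[0] and flags[1]

    def test_empty_peaks_rejected(self):
        with pytest.raises(DegenerateDataError):
            overlap_proportion([], [])

    def test_monotone_in_regions(self):
        r1 = [AnnotationRegion("chr1", 150, 400, "a")]
        r2 = r1 + [AnnotationRegion("chr2", 0, 60, "b")]
        f1, _ = overlap_proportion(_peaks(), r1)
        f2, _ = overlap_proportion(_peaks(), r2)
        assert f2 >= f1

    def test_order_invariant(self, rng):
        regions = [AnnotationRegion("chr1", 150, 400, "a"),
                   AnnotationRegion("chr2", 0, 60, "b")]
        f1, _ = overlap_proportion(_peaks(), regions)
        f2, _ = overlap_proportion(_peaks()[::-1], regions[::-1])
        assert f1 == f2


class TestNearest:
    def test_overlap_distance_zero(self):
        genes = [AnnotationRegion("chr1", 150, 400, "g")]
        d = nearest_feature_distance(_peaks()[:1], genes)
        assert d[0] == 0.0

    def test_gap_arithmetic(self):
        peaks = [PeakRegion("chr1", 100, 200, "p")]
        genes = [AnnotationRegion("chr1", 500, 900, "g")]
        assert nearest_feature_distance(peaks, genes)[0] == 300

    def test_exhaustive_minima(self):
        peaks = [PeakRegion("chr1", 0, 10, "a"),
                 PeakRegion("chr1", 500, 510, "b"),
                 PeakRegion("chr1", 2000, 2010, "c"),
                 PeakRegion("chr3", 0, 10, "d")]
        genes = [AnnotationRegion("chr1", 100, 200, "g1"),
                 AnnotationRegion("chr1", 505, 600, "g2"),
                 AnnotationRegion("chr2", 0, 10, "g3")]
        d = nearest_feature_distance(peaks, genes)
        assert d.tolist()[:3] == [90.0, 0.0, 1400.0]
        assert np.isinf(d[3])  # no features on chr3

    def test_symmetric_between_interval_sets(self):
        peaks = [PeakRegion("chr1", 100, 200, "p")]
        genes = [AnnotationRegion("chr1", 500, 900, "g")]
        d1 = nearest_feature_distance(peaks, genes)[0]
        d2 = nearest_feature_distance(
            [PeakRegion("chr1", 500, 900, "g")],
            [AnnotationRegion("chr1", 100, 200, "p")])[0]
        assert d1 == d2


class TestEdsWindows:
    def _genes(self):
        return pd.DataFrame({
            "gene": ["g1", "g2", "g3", "g4", "g5"],
            "chrom": ["chr1"] * 4 + ["chr2"],
            "start": [1000, 300_000, 600_000, 600_000, 1000],
            "end": [2000, 301_000, 601_000, 601_000, 2000],
            "eds_score": [0.9, 0.5, 0.7, 0.7, 0.1]})

    def test_hand_tallied_counts(self):
        # centers: p1 1500 (g1 window), p2 250000 (g2), p3 50000 (g1),
        # p4 5_000_000 (none), p5 chr2 1500 (g5), p6 650000 (g3, g4 dup)
        peaks = [PeakRegion("chr1", 1000, 2000, "p1"),
                 PeakRegion("chr1", 249_000, 251_000, "p2"),
                 PeakRegion("chr1", 49_000, 51_000, "p3"),
                 PeakRegion("chr1", 4_999_000, 5_001_000, "p4"),
                 PeakRegion("chr2", 1000, 2000, "p5"),
                 PeakRegion("chr1", 649_000, 651_000, "p6")]
        genes, per_peak = eds_window_counts(peaks, self._genes(),
                                            flank_bp=100_000)
        counts = dict(zip(genes["gene"], genes["n_peaks"]))
        # duplicate transcript rows (g3/g4 share coordinates) both kept:
        # they differ by name, so deduplication keeps both labels
        assert counts == {"g1": 2, "g2": 1, "g3": 1, "g4": 1, "g5": 1}
        pk = dict(zip(per_peak["peak_id"], per_peak["n_genes"]))
        assert pk == {"p1": 1, "p2": 1, "p3": 1, "p4": 0, "p5": 1, "p6": 2}

    def test_duplicate_transcripts_dropped(self):
        genes = pd.concat([self._genes(), self._genes().iloc[[0]]])
        out, _ = eds_window_counts([PeakRegion("chr1", 0, 10, "p")], genes)
        assert (out["gene"] == "g1").sum() == 1

    def test_percentiles_span_table(self):
        out, _ = eds_window_counts([PeakRegion("chr1", 0, 10, "p")],
                                   self._genes())
        assert out["eds_percentile"].max() == 100.0
        assert out["eds_percentile"].min() > 0.0
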
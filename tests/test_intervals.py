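"""Genetic-map interpolation, IBD segment calling, and region algebra."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pedprio.intervals import (
    GeneticMap,
    IbdTrack,
    RegionSet,
    call_ibd_segments,
    call_ibd_segment_list,
    candidate_regions,
    interpolate_cm,
    intersect,
    read_bed,
    read_ibd_table,
    subtract,
    union,
    write_bed,
    write_ibd_table,
)

from conftest import random_region_set, random_track, region_mask


# ---------------------------------------------------------------------------
# genetic map
# ---------------------------------------------------------------------------

class TestGeneticMap:
    def test_midpoint_of_linear_segment(self):
        gmap = GeneticMap({"chr1": [(1_000_000, 1.0), (2_000_000, 3.0)]})
        assert interpolate_cm(gmap, "chr1", 1_500_000) == pytest.approx(2.0)

    def test_query_at_anchor_returns_anchor_cm(self):
        gmap = GeneticMap({"chr1": [(100, 0.5), (200, 1.5), (400, 4.0)]})
        for bp, cm in [(100, 0.5), (200, 1.5), (400, 4.0)]:
            assert interpolate_cm(gmap, "chr1", bp) == pytest.approx(cm)

    def test_clamped_outside_anchored_range(self):
        gmap = GeneticMap({"chr1": [(100, 1.0), (200, 2.0)]})
        assert interpolate_cm(gmap, "chr1", 1) == pytest.approx(1.0)
        assert interpolate_cm(gmap, "chr1", 10_000) == pytest.approx(2.0)

    def test_unknown_chromosome_named_in_error(self):
        gmap = GeneticMap({"chr1": [(100, 1.0), (200, 2.0)]})
        with pytest.raises(KeyError, match="chrX"):
            interpolate_cm(gmap, "chrX", 150)

    def test_rejects_degenerate_anchor_lists(self):
        with pytest.raises(ValueError, match=">= 2"):
            GeneticMap({"chr1": [(100, 1.0)]})
        with pytest.raises(ValueError, match="increasing"):
            GeneticMap({"chr1": [(100, 1.0), (100, 2.0)]})
        with pytest.raises(ValueError, match="decrease"):
            GeneticMap({"chr1": [(100, 2.0), (200, 1.0)]})

    def test_matches_independent_two_point_oracle(self, rng):
        """1000 random queries vs a brute-force flanking-anchor interpolation."""
        bp = np.sort(rng.choice(np.arange(1, 10**7), size=30, replace=False))
        cm = np.sort(rng.uniform(0, 150, size=30))
        gmap = GeneticMap({"chr1": list(zip(bp.tolist(), cm.tolist()))})

        def oracle(q):
            if q <= bp[0]:
                return cm[0]
            if q >= bp[-1]:
                return cm[-1]
            i = int(np.searchsorted(bp, q, side="right")) - 1
            if bp[i] == q:
                return cm[i]
            frac = (q - bp[i]) / (bp[i + 1] - bp[i])
            return cm[i] + frac * (cm[i + 1] - cm[i])

        queries = rng.integers(1, 10**7, size=1000)
        got = gmap.interpolate("chr1", queries)
        want = np.array([oracle(int(q)) for q in queries])
        assert np.max(np.abs(got - want)) < 1e-9


# ---------------------------------------------------------------------------
# segment calling
# ---------------------------------------------------------------------------

def _track(positions, p2):
    """Track on one chromosome with p2 as given, remainder on p0."""
    p2 = np.asarray(p2, dtype=float)
    arr = np.column_stack(
        [np.asarray(positions, float), 1.0 - p2, np.zeros_like(p2), p2]
    )
    return IbdTrack(("A", "B"), {"chr1": arr})


class TestSegmentCalling:
    def test_fully_shared_chromosome_is_one_segment(self):
        tr = _track([100, 500, 900], [1.0, 1.0, 1.0])
        regions = call_ibd_segments(tr)
        assert regions.intervals("chr1").tolist() == [[99, 900]]

    def test_fully_unshared_chromosome_is_empty(self):
        tr = _track([100, 500, 900], [0.0, 0.0, 0.0])
        assert call_ibd_segments(tr).is_empty()

    def test_empty_track_gives_empty_regions(self):
        assert call_ibd_segments(IbdTrack(("A", "B"), {})).is_empty()

    def test_threshold_is_strict(self):
        tr = _track([100, 200], [0.5, 0.5 + 1e-9])
        regions = call_ibd_segments(tr, threshold=0.5)
        # p1+p2 == 0.5 exactly does not qualify; the barely-above marker does
        assert regions.intervals("chr1").tolist() == [[199, 200]]

    def test_single_marker_run_is_one_bp(self):
        tr = _track([100, 500, 900], [0.0, 1.0, 0.0])
        assert call_ibd_segments(tr).intervals("chr1").tolist() == [[499, 500]]

    def test_segment_list_marker_counts(self):
        tr = _track([10, 20, 30, 40, 50], [1, 1, 0, 1, 0])
        segs = call_ibd_segment_list(tr)
        assert [(s.start, s.end, s.n_markers) for s in segs] == [(9, 20, 2), (39, 40, 1)]

    def test_matches_brute_force_run_scan(self, rng):
        """Random tracks vs an independent pass/fail-and-merge marker scan."""
        for _ in range(300):
            tr = random_track(rng)
            got = call_ibd_segments(tr, threshold=0.5)
            want = {}
            for chrom, arr in tr.markers.items():
                ivs = []
                run = []
                for pos, p0, p1, p2 in arr:
                    if p1 + p2 > 0.5:
                        run.append(int(pos))
                    else:
                        if run:
                            ivs.append((run[0] - 1, run[-1]))
                        run = []
                if run:
                    ivs.append((run[0] - 1, run[-1]))
                if ivs:
                    want[chrom] = ivs
            assert got == RegionSet(want)

    def test_total_length_monotone_in_threshold(self, rng):
        for _ in range(50):
            tr = random_track(rng)
            lengths = [
                call_ibd_segments(tr, threshold=t).total_length()
                for t in (0.2, 0.5, 0.8)
            ]
            assert lengths == sorted(lengths, reverse=True)


# ---------------------------------------------------------------------------
# region algebra
# ---------------------------------------------------------------------------

class TestRegionAlgebra:
    def test_normalisation_merges_overlaps_and_abutments(self):
        rs = RegionSet({"c": [(5, 10), (10, 15), (3, 6), (20, 25)]})
        assert rs.intervals("c").tolist() == [[3, 15], [20, 25]]

    def test_rejects_invalid_intervals(self):
        with pytest.raises(ValueError):
            RegionSet({"c": [(-1, 5)]})
        with pytest.raises(ValueError):
            RegionSet({"c": [(5, 3)]})

    def test_intersect_idempotent_and_disjoint(self, rng):
        a = random_region_set(rng)
        assert intersect(a, a) == a
        b = RegionSet({"other": [(0, 10)]})
        assert intersect(a, b).is_empty()

    def test_subtract_identities(self, rng):
        a = random_region_set(rng)
        assert subtract(a, a).is_empty()
        assert subtract(a, RegionSet()) == a

    def test_algebra_matches_per_base_oracle(self, rng):
        """intersect/subtract/union agree with boolean membership on every base."""
        size = 10_000
        for _ in range(200):
            a = random_region_set(rng, chroms=("c",), max_pos=size)
            b = random_region_set(rng, chroms=("c",), max_pos=size)
            ma, mb = region_mask(a, "c", size), region_mask(b, "c", size)
            assert np.array_equal(region_mask(intersect(a, b), "c", size), ma & mb)
            assert np.array_equal(region_mask(subtract(a, b), "c", size), ma & ~mb)
            assert np.array_equal(region_mask(union(a, b), "c", size), ma | mb)

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 2**31 - 1))
    def test_set_identities_hold(self, seed):
        rng = np.random.default_rng(seed)
        a = random_region_set(rng, chroms=("c",))
        b = random_region_set(rng, chroms=("c",))
        assert intersect(a, b) == intersect(b, a)
        assert intersect(subtract(a, b), b).is_empty()
        assert intersect(intersect(a, b), a) == intersect(a, b)  # (a∩b) ⊆ a

    def test_contains_uses_one_based_positions(self):
        rs = RegionSet({"c": [(99, 200)]})  # markers 100..200 inclusive, 1-based
        assert rs.contains("c", 100) and rs.contains("c", 200)
        assert not rs.contains("c", 99) and not rs.contains("c", 201)


# ---------------------------------------------------------------------------
# candidate regions (patient sharing minus sib sharing)
# ---------------------------------------------------------------------------

class TestCandidateRegions:
    def test_no_sibs_returns_patient_sharing(self, rng):
        tr = random_track(rng)
        assert candidate_regions(tr, []) == call_ibd_segments(tr)

    def test_sib_sharing_everything_gives_empty(self, rng):
        tr = random_track(rng)
        assert candidate_regions(tr, [(tr, tr)]).is_empty()

    def test_missing_sib_track_is_an_error(self, rng):
        tr = random_track(rng)
        with pytest.raises(ValueError, match="two tracks"):
            candidate_regions(tr, [(tr, None)])

    def test_matches_independent_composition(self, rng):
        """Random tracks vs an independently coded S − ⋃(S∩sib1∩sib2)."""
        for _ in range(100):
            pt = random_track(rng)
            sibs = [(random_track(rng), random_track(rng)) for _ in range(2)]
            got = candidate_regions(pt, sibs)
            S = call_ibd_segments(pt)
            acc = S
            for t1, t2 in sibs:
                both = intersect(call_ibd_segments(t1), call_ibd_segments(t2))
                acc = subtract(acc, intersect(S, both))
            assert got == acc
            # the invariant: candidates never exceed patient sharing
            assert intersect(got, S) == got


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

class TestIbdIO:
    def test_round_trip_preserves_values(self, tmp_path, rng):
        tr = random_track(rng)
        path = tmp_path / "ibd.tsv"
        write_ibd_table([tr], path)
        (back,) = read_ibd_table(path)
        assert back.pair == tr.pair
        for chrom in tr.markers:
            assert np.allclose(back.markers[chrom], tr.markers[chrom], atol=0)

    def test_bad_probability_sum_rejected_with_line_number(self, tmp_path):
        path = tmp_path / "ibd.tsv"
        path.write_text(
            "A,B\tchr1\t100\t0.5\t0.3\t0.2\n"
            "A,B\tchr1\t200\t0.5\t0.2\t0.1\n"  # sums to 0.8
        )
        with pytest.raises(ValueError, match=":2"):
            read_ibd_table(path)

    def test_malformed_line_rejected_with_line_number(self, tmp_path):
        path = tmp_path / "ibd.tsv"
        path.write_text("A,B\tchr1\t100\t0.5\t0.5\n")
        with pytest.raises(ValueError, match=":1"):
            read_ibd_table(path)

    def test_bed_uses_zero_based_half_open(self, tmp_path):
        """Markers at 1-based 100..200 map to the BED row 'chr 99 200'."""
        tr = _track([100, 150, 200], [1.0, 1.0, 1.0])
        path = tmp_path / "r.bed"
        write_bed(call_ibd_segments(tr), path)
        assert path.read_text() == "chr1\t99\t200\n"
        assert read_bed(path) == RegionSet({"chr1": [(99, 200)]})
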
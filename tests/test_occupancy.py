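"""Summit colocalization, boundary occupancy classes, and class stratification."""

import numpy as np
import pytest

from tadbound.formats import Peak, PeakSet
from tadbound.insulation import InsulationTrack
from tadbound.occupancy import (
    boundary_occupancy,
    colocalize_summits,
    correlate_intensity,
    distance_to_nearest_peak,
    stratify_by_class,
    upset_counts,
)
from tadbound.synthetic import evenly_spaced_layout, gen_peaks


def make_peakset(factor, summit_positions, chrom="chrS", height=10.0):
    peaks = []
    for k, s in enumerate(summit_positions):
        s = int(s)
        peaks.append(Peak(chrom=chrom, start=s - 50, end=s + 50, summit=50,
                          height=height, factor=factor, name=f"{factor}_{k}"))
    return PeakSet(factor=factor, peaks=peaks)


def brute_force_partition(positions, radius):
    """Transitive closure of the pairwise |a - b| <= radius relation (O(n^2))."""
    n = len(positions)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if abs(positions[i] - positions[j]) <= radius:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return sorted(frozenset(g) for g in groups.values())


class TestColocalizeSummits:
    def test_within_radius_forms_one_group(self):
        sets = {"A": make_peakset("A", [1000]), "B": make_peakset("B", [1150])}
        groups = colocalize_summits(sets, radius=200)
        assert len(groups) == 1
        assert groups[0].label == frozenset({"A", "B"})

    def test_beyond_radius_stays_separate(self):
        sets = {"A": make_peakset("A", [1000]), "B": make_peakset("B", [1300])}
        groups = colocalize_summits(sets, radius=200)
        assert sorted(g.label for g in groups) == [frozenset({"A"}),
                                                   frozenset({"B"})]

    def test_partition_matches_transitive_closure_oracle(self):
        rng = np.random.default_rng(0)
        for trial in range(10):
            positions = np.sort(rng.integers(0, 40_000, size=200))
            factors = rng.choice(["A", "B", "C"], size=200)
            sets = {f: make_peakset(f, positions[factors == f])
                    for f in "ABC"}
            groups = colocalize_summits(sets, radius=200)
            got = sorted(frozenset(np.flatnonzero(np.isin(positions, g.positions)
                                                  ).tolist())
                         for g in groups)
            assert got == brute_force_partition(positions.tolist(), 200)

    def test_order_independence(self):
        rng = np.random.default_rng(1)
        positions = rng.integers(0, 100_000, size=100)
        fwd = {"A": make_peakset("A", positions[:50]),
               "B": make_peakset("B", positions[50:])}
        rev = {"B": make_peakset("B", positions[50:][::-1]),
               "A": make_peakset("A", positions[:50][::-1])}
        ga = colocalize_summits(fwd)
        gb = colocalize_summits(rev)
        assert sorted((g.label, tuple(sorted(g.positions))) for g in ga) == \
               sorted((g.label, tuple(sorted(g.positions))) for g in gb)

    def test_single_factor_no_background_upset_is_one_singleton_row(self):
        layout = evenly_spaced_layout(n_boundaries=5, n_bins=500)
        sets = gen_peaks(layout, {int(b): {"CTCF"} for b in layout.boundary_bins},
                         jitter_sd=0, n_background=0, seed=0)
        sets = {"CTCF": sets["CTCF"]}
        table = upset_counts(colocalize_summits(sets))
        assert table["label"].tolist() == ["CTCF"]
        assert table["count"].tolist() == [5]


class TestBoundaryOccupancy:
    def test_half_open_window_convention(self):
        pos = 100_000
        window = 10_000
        inside = make_peakset("A", [pos - window // 2])
        outside = make_peakset("B", [pos + window // 2])
        occ = boundary_occupancy([pos], {"A": inside, "B": outside}, window=window)
        assert occ.loc[0, "label"] == "A"
        assert occ.loc[0, "n_A"] == 1 and occ.loc[0, "n_B"] == 0

    def test_no_peaks_means_unbound_everywhere(self):
        occ = boundary_occupancy([10_000, 20_000],
                                 {"A": PeakSet(factor="A", peaks=[])})
        assert (occ["label"] == "").all()
        assert (occ["n_factors"] == 0).all()

    def test_planted_classes_recovered_exactly_without_jitter(self):
        layout = evenly_spaced_layout(n_boundaries=8, n_bins=800)
        combos = [{"BEAF-32", "CP190"}, {"CTCF"}, {"BEAF-32", "CTCF",
                                                   "Su(Hw)", "CP190"}, set()]
        assignment = {int(b): combos[i % len(combos)]
                      for i, b in enumerate(layout.boundary_bins)}
        sets = gen_peaks(layout, assignment, jitter_sd=0, n_background=0, seed=0)
        occ = boundary_occupancy(layout.boundary_positions, sets)
        for i, b in enumerate(layout.boundary_bins):
            assert occ.loc[i, "label"] == "+".join(sorted(assignment[int(b)]))

    def test_classes_partition_the_boundaries(self):
        layout = evenly_spaced_layout(n_boundaries=10, n_bins=1000)
        assignment = {int(b): {"CTCF", "CP190"} for b in layout.boundary_bins}
        sets = gen_peaks(layout, assignment, jitter_sd=2000, n_background=30,
                         seed=3)
        occ = boundary_occupancy(layout.boundary_positions, sets)
        assert occ["label"].value_counts().sum() == len(layout.boundary_bins)

    def test_nonpositive_window_rejected(self):
        with pytest.raises(ValueError):
            boundary_occupancy([1000], {"A": PeakSet(factor="A", peaks=[])},
                               window=0)


class TestStratifyByClass:
    def _track(self, scores):
        scores = np.asarray(scores, dtype=float)
        return InsulationTrack(chrom="c", bin_size=10_000, windows=(100_000,),
                               score=scores, valid=np.isfinite(scores))

    def test_identical_distributions_give_ks_zero(self):
        layout = evenly_spaced_layout(n_boundaries=6, n_bins=600)
        sets = {"A": make_peakset("A", layout.boundary_positions[:3]),
                "B": make_peakset("B", layout.boundary_positions[3:])}
        occ = boundary_occupancy(layout.boundary_positions, sets)
        scores = np.zeros(600)
        scores[layout.boundary_bins] = [-0.5, -0.3, -0.1, -0.5, -0.3, -0.1]
        table, tests = stratify_by_class(layout.boundary_positions.tolist(),
                                         self._track(scores), occ)
        assert tests[("A", "B")].statistic == 0.0

    def test_small_classes_flagged_not_tested(self):
        layout = evenly_spaced_layout(n_boundaries=3, n_bins=300)
        sets = {"A": make_peakset("A", layout.boundary_positions[:1]),
                "B": make_peakset("B", layout.boundary_positions[1:])}
        occ = boundary_occupancy(layout.boundary_positions, sets)
        track = self._track(np.zeros(300))
        table, tests = stratify_by_class(layout.boundary_positions.tolist(),
                                         track, occ)
        assert not table.loc[table["label"] == "A", "testable"].iloc[0]
        assert tests == {}

    def test_classes_ordered_by_median_score(self):
        layout = evenly_spaced_layout(n_boundaries=6, n_bins=600)
        sets = {"A": make_peakset("A", layout.boundary_positions[:3]),
                "B": make_peakset("B", layout.boundary_positions[3:])}
        occ = boundary_occupancy(layout.boundary_positions, sets)
        scores = np.zeros(600)
        scores[layout.boundary_bins[:3]] = -1.0   # A boundaries insulate more
        scores[layout.boundary_bins[3:]] = -0.1
        table, _ = stratify_by_class(layout.boundary_positions.tolist(),
                                     self._track(scores), occ)
        assert table["label"].tolist() == ["A", "B"]

    def test_heights_independent_of_insulation_are_uncorrelated(self):
        rng = np.random.default_rng(4)
        n = 500
        positions = np.arange(n) * 40_000 + 20_000
        bins = positions // 10_000
        peaks = []
        for k, p in enumerate(positions):
            peaks.append(Peak(chrom="chrS", start=int(p) - 50, end=int(p) + 50,
                              summit=50, height=float(rng.lognormal(3, 1)),
                              factor="A", name=f"A_{k}"))
        sets = {"A": PeakSet(factor="A", peaks=peaks)}
        scores = np.zeros(int(bins.max()) + 10)
        scores[bins] = rng.normal(-0.5, 0.2, size=n)
        r = correlate_intensity(positions.tolist(), sets,
                                self._track(scores))["A"]
        assert abs(r) < 0.15


class TestDistanceToNearestPeak:
    def test_summit_at_boundary_gives_zero(self):
        ps = make_peakset("A", [50_000])
        dq, db, _ = distance_to_nearest_peak([50_000], ps, [60_000])
        assert dq[0] == 0.0 and db[0] == 10_000.0

    def test_matches_linear_scan_oracle(self):
        rng = np.random.default_rng(5)
        summits = rng.integers(0, 1_000_000, size=50)
        ps = make_peakset("A", summits)
        queries = rng.integers(0, 1_000_000, size=30).tolist()
        dq, _, _ = distance_to_nearest_peak(queries, ps, queries)
        for q, d in zip(queries, dq):
            assert d == min(abs(int(s) - q) for s in summits)

    def test_identical_sets_give_ks_zero(self):
        ps = make_peakset("A", [10_000, 90_000])
        q = [15_000, 40_000, 88_000]
        _, _, res = distance_to_nearest_peak(q, ps, q)
        assert res.statistic == 0.0

    def test_empty_peakset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            distance_to_nearest_peak([1000], PeakSet(factor="A", peaks=[]),
                                     [2000])
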
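"""Richness, partitions, dissimilarity, correlogram, rarefaction, census."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ednameta.decontam import DetectionMatrix
from ednameta.stats import (
    CensusTable,
    accumulation_curve,
    bray_curtis,
    chao1,
    detection_efficiency,
    detection_rate,
    mantel_correlogram,
    partition_by_layer,
    partition_from_sets,
    replicate_accumulation,
    station_group_counts,
)


def matrix_from_detections(rows):
    """rows: (station, layer, replicate, taxon) detected entries."""
    frame = pd.DataFrame(
        [
            {
                "station": s,
                "layer": layer,
                "replicate": r,
                "sample_id": f"{s}-{layer}-{r}",
                "taxon": t,
                "reads": 100,
                "detected": True,
            }
            for s, layer, r, t in rows
        ]
    )
    return DetectionMatrix(frame, cutoff_fraction=0.0)


class TestChao1:
    def test_no_singletons_returns_observed_richness(self):
        inc = np.ones((10, 3), dtype=bool)
        est = chao1(inc)
        assert est.f1 == 0 and est.chao1 == est.s_obs == 10

    def test_bias_corrected_closed_form(self):
        # 10 species observed, 4 singletons, 2 doubletons: 10 + 4*3/6 = 12
        inc = np.zeros((10, 3), dtype=bool)
        inc[:4, 0] = True
        inc[4:6, :2] = True
        inc[6:, :] = True
        est = chao1(inc)
        assert (est.s_obs, est.f1, est.f2) == (10, 4, 2)
        assert est.chao1 == pytest.approx(12.0)

    def test_defined_without_doubletons(self):
        # 5 species, all singletons: 5 + 5*4/2 = 15
        inc = np.eye(5, 3, dtype=bool)
        inc[3, 0] = True
        inc[4, 0] = True
        est = chao1(inc)
        assert (est.f1, est.f2) == (5, 0)
        assert est.chao1 == pytest.approx(15.0)

    def test_classic_form_diverges_without_doubletons(self):
        inc = np.eye(3, 3, dtype=bool)
        assert math.isinf(chao1(inc, bias_corrected=False).chao1)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 5000))
    def test_never_below_observed_richness(self, seed):
        rng = np.random.default_rng(seed)
        inc = rng.random((rng.integers(1, 12), 3)) < 0.5
        est = chao1(inc)
        assert est.chao1 >= est.s_obs
        assert est.f1 + est.f2 <= est.s_obs


class TestReplicateAccumulation:
    def test_identical_replicates_are_flat(self):
        rows = [("St1", "surface", r, "Sp a") for r in (1, 2, 3)]
        acc = replicate_accumulation(matrix_from_detections(rows), "surface")
        assert list(acc["mean_species"]) == [1.0, 1.0, 1.0]

    def test_disjoint_replicates_accumulate_linearly(self):
        rows = [("St1", "surface", r, sp) for r, sp in [(1, "A"), (2, "B"), (3, "C")]]
        acc = replicate_accumulation(matrix_from_detections(rows), "surface")
        assert list(acc["mean_species"]) == [1.0, 2.0, 3.0]

    def test_subset_enumeration_matches_hand_counts(self):
        # replicate sets {A,B}, {A}, {A}: k=1 mean 4/3, k=3 union 2
        rows = [
            ("St1", "surface", 1, "A"),
            ("St1", "surface", 1, "B"),
            ("St1", "surface", 2, "A"),
            ("St1", "surface", 3, "A"),
        ]
        acc = replicate_accumulation(matrix_from_detections(rows), "surface")
        assert acc["mean_species"].iloc[0] == pytest.approx(4 / 3)
        assert acc["mean_species"].iloc[2] == pytest.approx(2.0)


class TestPartition:
    def test_all_species_in_both_layers(self):
        rows = [("St1", layer, 1, sp) for layer in ("surface", "bottom") for sp in "ABC"]
        p = partition_by_layer(matrix_from_detections(rows))
        assert (p.surface_only, p.bottom_only, p.both) == (0, 0, 3)

    def test_published_marginals_give_half_shared(self):
        # 97 surface species and 95 bottom species overlapping in 64 ->
        # 33 surface-only, 31 bottom-only, 64 shared of 128 total
        surface = {f"sp{i}" for i in range(97)}
        bottom = {f"sp{i}" for i in range(33, 128)}
        p = partition_from_sets(surface, bottom)
        assert (p.surface_only, p.bottom_only, p.both) == (33, 31, 64)
        assert p.total_species == 128

    def test_empty_matrix(self):
        m = DetectionMatrix(
            pd.DataFrame(
                columns=["station", "layer", "replicate", "sample_id", "taxon", "reads", "detected"]
            ).astype({"detected": bool}),
            0.0,
        )
        p = partition_by_layer(m)
        assert (p.surface_only, p.bottom_only, p.both) == (0, 0, 0)

    def test_partition_sums_to_species_total(self, small_run):
        p = small_run.stats["partition"]
        assert p.total_species == len(small_run.detection.all_species())


class TestStationGroups:
    def test_group_counts_and_set_logic(self):
        rows = [
            ("St1", "surface", 1, "m1"),
            ("St1", "surface", 1, "m2"),
            ("St1", "bottom", 1, "f1"),
            ("St2", "surface", 1, "w1"),
        ]
        m = matrix_from_detections(rows)
        habitat = {"m1": "marine", "m2": "marine", "f1": "marine", "w1": "freshwater"}
        counts = station_group_counts(m, habitat, fishery={"m1", "f1"}).set_index("station")
        assert counts.loc["St1", "all_fish"] == 3
        assert counts.loc["St1", "fishery"] == 2
        assert counts.loc["St1", "freshwater"] == 0
        assert counts.loc["St2", "freshwater"] == 1
        assert (counts["fishery"] + counts["freshwater"] <= counts["all_fish"]).all()


class TestBrayCurtis:
    def test_known_value(self):
        assert bray_curtis([2, 1, 0], [1, 1, 1]) == pytest.approx(2 / 6)

    def test_identity_and_disjoint_support(self):
        assert bray_curtis([3, 4], [3, 4]) == 0.0
        assert bray_curtis([3, 0], [0, 5]) == 1.0

    def test_double_zero_undefined(self):
        with pytest.raises(ValueError, match="all-zero"):
            bray_curtis([0, 0], [0, 0])

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(0, 50), min_size=2, max_size=8),
        st.lists(st.integers(0, 50), min_size=2, max_size=8),
    )
    def test_symmetric_and_bounded(self, x, y):
        n = min(len(x), len(y))
        x, y = x[:n], y[:n]
        if sum(x) + sum(y) == 0:
            return
        d = bray_curtis(x, y)
        assert 0.0 <= d <= 1.0
        assert d == pytest.approx(bray_curtis(y, x))
        assert (d == 0.0) == (x == y)


class TestMantelCorrelogram:
    @staticmethod
    def clustered_data():
        """Two spatial clusters with distinct compositions."""
        coords = np.array([[0, 0], [50, 0], [0, 50], [2000, 2000], [2050, 2000]])
        comm = np.array(
            [
                [5, 4, 0, 0],
                [4, 5, 0, 0],
                [5, 5, 1, 0],
                [0, 0, 5, 4],
                [0, 1, 4, 5],
            ],
            dtype=float,
        )
        return comm, coords

    def test_short_range_class_shows_positive_autocorrelation(self):
        comm, coords = self.clustered_data()
        res = mantel_correlogram(comm, coords, n_classes=3, n_perm=199, seed=0)
        first = res.classes[0]
        assert first.mantel_r > 0  # nearby pairs more similar than average
        assert first.p_value is not None

    def test_exhaustive_permutation_p_matches_manual_enumeration(self):
        """Permutation p on 5 stations against full 120-permutation brute force."""
        from scipy.spatial.distance import pdist, squareform

        comm, coords = self.clustered_data()
        res = mantel_correlogram(comm, coords, n_classes=3, exhaustive=True)

        dmat = squareform(pdist(comm, "braycurtis"))
        gmat = squareform(pdist(coords))
        iu = np.triu_indices(5, 1)
        edges = np.linspace(0, gmat[iu].max() * (1 + 1e-9), 4)
        for ci, cls in enumerate(res.classes):
            lo, hi = edges[cls.index], edges[cls.index + 1]
            w = (gmat[iu] >= lo) & (
                gmat[iu] <= hi if cls.index == 2 else gmat[iu] < hi
            )
            def stat(perm):
                dp = dmat[np.ix_(perm, perm)][iu]
                wv = w.astype(float)
                return -np.corrcoef(dp, wv)[0, 1]
            r_obs = stat(range(5))
            assert r_obs == pytest.approx(cls.mantel_r)
            perms = list(itertools.permutations(range(5)))
            exceed = sum(
                abs(stat(p)) >= abs(r_obs) - 1e-12 for p in perms[1:]
            )
            assert cls.p_value == pytest.approx((exceed + 1) / len(perms))

    def test_sampled_p_consistent_with_exhaustive(self):
        comm, coords = self.clustered_data()
        exact = mantel_correlogram(comm, coords, n_classes=3, exhaustive=True)
        sampled = mantel_correlogram(comm, coords, n_classes=3, n_perm=999, seed=1)
        for e, s in zip(exact.classes, sampled.classes):
            assert s.p_value == pytest.approx(e.p_value, abs=0.08)

    def test_zero_permutations_report_no_p(self):
        comm, coords = self.clustered_data()
        res = mantel_correlogram(comm, coords, n_classes=3, n_perm=0)
        assert all(c.p_value is None for c in res.classes)
        assert all(np.isfinite(c.mantel_r) for c in res.classes)

    def test_pair_counts_partition_all_pairs(self):
        comm, coords = self.clustered_data()
        res = mantel_correlogram(comm, coords, n_classes=3, n_perm=0)
        assert sum(c.n_pairs for c in res.classes) == 10

    def test_too_few_stations_rejected(self):
        with pytest.raises(ValueError, match="4 stations"):
            mantel_correlogram(np.ones((3, 2)), np.zeros((3, 2)))


def test_correlogram_matches_independent_mantel_statistic():
    """Cross-check the per-class statistic against scikit-bio's Mantel test."""
    skbio_stats = pytest.importorskip("skbio.stats.distance")
    from scipy.spatial.distance import pdist, squareform

    rng = np.random.default_rng(4)
    comm = rng.random((8, 5)) + 0.2
    coords = rng.random((8, 2)) * 1000
    res = mantel_correlogram(comm, coords, n_classes=3, n_perm=0)
    dmat = squareform(pdist(comm, "braycurtis"))
    gmat = squareform(pdist(coords))
    iu = np.triu_indices(8, 1)
    edges = np.linspace(0, gmat[iu].max() * (1 + 1e-9), 4)
    for cls in res.classes:
        lo, hi = edges[cls.index], edges[cls.index + 1]
        w = (gmat[iu] >= lo) & (gmat[iu] <= hi if cls.index == 2 else gmat[iu] < hi)
        model = squareform(w.astype(float))
        r, _, _ = skbio_stats.mantel(
            skbio_stats.DistanceMatrix(dmat),
            skbio_stats.DistanceMatrix(model),
            method="pearson",
            permutations=0,
        )
        assert cls.mantel_r == pytest.approx(-r)


class TestAccumulation:
    def census(self, incidence):
        rows = []
        for c, row in enumerate(incidence):
            for s, present in enumerate(row):
                rows.append(
                    {"census_id": f"c{c:02d}", "species": f"sp{s}", "count": int(bool(present))}
                )
        return CensusTable(pd.DataFrame(rows))

    def test_ubiquitous_species_contributes_one_everywhere(self):
        inc = [[1, 0], [1, 0], [1, 1]]
        curve = accumulation_curve(self.census(inc))
        # species 0 in all censuses: S(t) >= 1 exactly from t = 1
        assert curve.s_mean[0] >= 1.0
        assert curve.s_mean[-1] == pytest.approx(2.0)

    def test_single_occurrence_species_contributes_t_over_T(self):
        inc = [[1], [0], [0], [0]]
        curve = accumulation_curve(self.census(inc))
        for t in range(1, 5):
            assert curve.s_mean[t - 1] == pytest.approx(t / 4)

    def test_final_point_equals_observed_total(self):
        rng = np.random.default_rng(1)
        inc = (rng.random((12, 15)) < 0.3).astype(int)
        inc[0, :3] = 1
        curve = accumulation_curve(self.census(inc))
        observed = (np.asarray(inc).sum(axis=0) > 0).sum()
        assert curve.s_mean[-1] == pytest.approx(observed)
        assert np.all(np.diff(curve.s_mean) >= -1e-9)

    def test_matches_resampled_orderings_within_two_percent(self):
        """Closed form vs the mean over 1,000 random census orderings."""
        rng = np.random.default_rng(7)
        inc = rng.random((12, 15)) < 0.35
        inc[:, 0] = True
        curve = accumulation_curve(self.census(inc.astype(int)))
        big_t = inc.shape[0]
        acc = np.zeros(big_t)
        resample_rng = np.random.default_rng(1234)
        for _ in range(1000):
            order = resample_rng.permutation(big_t)
            seen = np.zeros(inc.shape[1], dtype=bool)
            for t, c in enumerate(order):
                seen |= inc[c]
                acc[t] += seen.sum()
        resampled = acc / 1000
        np.testing.assert_allclose(curve.s_mean, resampled, rtol=0.02)

    def test_variance_tracks_resampled_spread(self):
        rng = np.random.default_rng(9)
        inc = rng.random((10, 12)) < 0.3
        inc[:, 0] = True
        curve = accumulation_curve(self.census(inc.astype(int)))
        assert curve.s_var[-1] == pytest.approx(0.0, abs=1e-9)
        assert (curve.s_var >= -1e-9).all()


class TestCensusComparison:
    def test_published_detection_rate_arithmetic(self):
        # 40 of 80 observed species detected, 7 without reference barcodes
        observed = {f"sp{i}" for i in range(80)}
        detected = {f"sp{i}" for i in range(40)}
        no_ref = {f"sp{i}" for i in range(73, 80)}
        rate = detection_rate(observed, detected, no_ref)
        assert rate.rate_all == 54.8

    def test_full_and_zero_detection(self):
        observed = {"a", "b"}
        assert detection_rate(observed, {"a", "b", "c"}).rate_all == 100.0
        assert detection_rate(observed, set()).rate_all == 0.0

    def test_strict_rate_excludes_indistinguishable(self):
        observed = {f"sp{i}" for i in range(10)}
        detected = {f"sp{i}" for i in range(4)}
        rate = detection_rate(observed, detected, indistinguishable={"sp8", "sp9"})
        assert rate.rate_all == 40.0
        assert rate.rate_strict == 50.0

    def test_efficiency_threshold_crossing(self):
        from ednameta.stats import AccumulationCurve

        c = AccumulationCurve(np.arange(1, 5), np.array([5, 8, 10, 11.0]), np.zeros(4))
        assert detection_efficiency(c, 10).requisite_censuses == 3
        assert detection_efficiency(c, 4).requisite_censuses == 1
        not_reached = detection_efficiency(c, 12)
        assert not not_reached.reached
        assert not_reached.s_final == pytest.approx(11.0)
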
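"""Replicate statistics, curvature-preference calls and vesiculation metrics."""
import numpy as np
import pytest
from scipy import stats as sps

from liponta import (
    BindingModel,
    BoxStats,
    DetectionModel,
    PopulationSpec,
    SimulatedSample,
    VesiculationModel,
    anova_oneway,
    bin_diameters,
    bin_sizes,
    box_stats,
    classify_preference,
    compare_efficiency,
    curvature_preference,
    pairwise_bonferroni,
    sample_population,
    significance_tier,
    simulate_experiment,
    size_tracks,
    vesiculate,
    vesiculation_dose_response,
)
from liponta.simulate import AcquisitionConfig
from tests.conftest import make_dist


def brute_force_anova(groups):
    """Textbook sums-of-squares ANOVA, written with plain loops."""
    values = [v for g in groups for v in g]
    grand = sum(values) / len(values)
    ssb = sum(len(g) * ((sum(g) / len(g)) - grand) ** 2 for g in groups)
    ssw = sum((v - sum(g) / len(g)) ** 2 for g in groups for v in g)
    df_b = len(groups) - 1
    df_w = len(values) - len(groups)
    f = (ssb / df_b) / (ssw / df_w)
    return f, float(sps.f.sf(f, df_b, df_w))


def brute_force_pairwise(groups, pairs):
    """Pooled-variance post-hoc t-tests with Bonferroni cap, plain loops."""
    ssw = sum((v - sum(g) / len(g)) ** 2 for g in groups.values() for v in g)
    df_w = sum(len(g) for g in groups.values()) - len(groups)
    ms_w = ssw / df_w
    out = {}
    for a, b in pairs:
        ga, gb = groups[a], groups[b]
        se = (ms_w * (1 / len(ga) + 1 / len(gb))) ** 0.5
        t = (sum(ga) / len(ga) - sum(gb) / len(gb)) / se
        out[(a, b)] = min(1.0, len(pairs) * 2 * float(sps.t.sf(abs(t), df_w)))
    return out


class TestAnova:
    def test_identical_groups(self):
        assert anova_oneway([[1, 2, 3], [1, 2, 3]]) == (0.0, 1.0)

    def test_matches_brute_force_on_simple_groups(self):
        groups = [[1, 2, 3], [2, 3, 4], [3, 4, 5]]
        f, p = anova_oneway(groups)
        f_ref, p_ref = brute_force_anova(groups)
        assert f == pytest.approx(f_ref, rel=1e-12)
        assert p == pytest.approx(p_ref, rel=1e-12)

    def test_matches_brute_force_and_scipy_on_random_instances(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            k = rng.integers(2, 5)
            groups = [rng.normal(rng.normal(0, 2), 1, rng.integers(3, 8)).tolist() for _ in range(k)]
            f, p = anova_oneway(groups)
            f_ref, p_ref = brute_force_anova(groups)
            assert f == pytest.approx(f_ref, rel=1e-10)
            assert p == pytest.approx(p_ref, rel=1e-10)
            f_sp, p_sp = sps.f_oneway(*groups)
            assert f == pytest.approx(float(f_sp), rel=1e-10)
            assert p == pytest.approx(float(p_sp), rel=1e-10)

    def test_translation_invariance(self):
        groups = [[1.0, 2.5, 3.0], [2.0, 4.0, 4.5]]
        shifted = [[v + 17.3 for v in g] for g in groups]
        assert anova_oneway(groups)[0] == pytest.approx(anova_oneway(shifted)[0], rel=1e-12)

    def test_zero_within_variance_different_means(self):
        f, p = anova_oneway([[1.0, 1.0], [2.0, 2.0]])
        assert f == np.inf and p == 0.0

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError):
            anova_oneway([[1.0], [2.0, 3.0]])
        with pytest.raises(ValueError):
            anova_oneway([[1.0, 2.0]])


class TestPairwiseBonferroni:
    def test_single_comparison_equals_raw_p(self):
        groups = {"a": [1.0, 2.0, 3.0], "b": [2.5, 3.5, 4.5]}
        adj = pairwise_bonferroni(groups, [("a", "b")])
        ref = brute_force_pairwise(groups, [("a", "b")])
        assert adj[("a", "b")] == pytest.approx(ref[("a", "b")], rel=1e-12)

    def test_bonferroni_caps_at_one(self):
        groups = {"a": [1.0, 2.0, 3.0], "b": [1.2, 2.2, 3.2], "c": [1.0, 2.1, 3.1], "d": [0.9, 2.0, 3.0]}
        pairs = [("a", "b"), ("a", "c"), ("a", "d"), ("b", "c")]
        adj = pairwise_bonferroni(groups, pairs)
        assert all(p == 1.0 for p in adj.values())

    def test_equal_groups_give_p_one(self):
        groups = {"a": [1.0, 2.0], "b": [1.0, 2.0]}
        assert pairwise_bonferroni(groups, [("a", "b")])[("a", "b")] == 1.0

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            groups = {
                name: rng.normal(rng.normal(0, 1), 1, rng.integers(3, 7)).tolist()
                for name in "abc"
            }
            pairs = [("a", "b"), ("b", "c")]
            adj = pairwise_bonferroni(groups, pairs)
            ref = brute_force_pairwise(groups, pairs)
            for pair in pairs:
                assert adj[pair] == pytest.approx(ref[pair], rel=1e-10)

    def test_unknown_group_rejected(self):
        with pytest.raises(KeyError):
            pairwise_bonferroni({"a": [1, 2], "b": [3, 4]}, [("a", "z")])

    def test_empty_comparisons_rejected(self):
        with pytest.raises(ValueError):
            pairwise_bonferroni({"a": [1, 2], "b": [3, 4]}, [])


def test_significance_tiers():
    assert [significance_tier(p) for p in (0.5, 0.04, 0.009, 0.0009, 0.00009)] == [
        "ns", "*", "**", "***", "****",
    ]


def _boxes(modes):
    return [BoxStats(mode=m, lower=m - 20, upper=m + 20) for m in modes]


class TestClassifyPreference:
    def test_identical_modes_give_none(self):
        call = classify_preference(_boxes([150, 155, 150]), _boxes([150, 155, 150]))
        assert call.label == "none"
        assert call.mode_shift == 0.0

    def test_clear_downward_shift_is_smaller(self):
        call = classify_preference(_boxes([200, 205, 200]), _boxes([100, 105, 100]))
        assert call.label == "smaller"
        assert call.mode_shift == pytest.approx(-100.0)

    def test_clear_upward_shift_is_larger(self):
        call = classify_preference(_boxes([200, 205, 200]), _boxes([400, 410, 405]))
        assert call.label == "larger"

    def test_small_shift_below_one_bin_is_none(self):
        call = classify_preference(_boxes([200.0, 200.0, 205.0]), _boxes([202.5, 202.5, 207.5]))
        assert call.label == "none"  # 2.5 nm < one bin width

    def test_replicate_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            classify_preference(_boxes([1, 2, 3]), _boxes([1, 2]))

    def test_bonferroni_over_conditions(self):
        data = {
            "800": (_boxes([200, 205, 200]), _boxes([100, 105, 100])),
            "200": (_boxes([150, 155, 150]), _boxes([150, 155, 150])),
        }
        calls = curvature_preference(data)
        assert [c.label for c in calls] == ["smaller", "none"]
        single = classify_preference(*data["800"])
        assert calls[0].p_adjusted == pytest.approx(min(1.0, 2 * single.p_adjusted))


def _experiment_modes(kind, seeds, n_particles=6000):
    """Total and bound replicate box stats from the full simulator pipeline.

    Conditions of a typical run: several thousand particles sized per
    recording, ~100-frame tracks. The binding midpoint sits below the
    population mode for a high-curvature binder (it labels the small tail)
    and above it for a low-curvature binder (an I-BAR-like protein bound
    only to the largest liposomes).
    """
    spec = PopulationSpec(components=((250.0, 1.45, 1.0),), extrusion_cutoff=800.0)
    midpoint = 350.0 if kind == "low_curvature" else 150.0
    binding = BindingModel(kind=kind, midpoint=midpoint, steepness=5.0, max_prob=0.9, baseline_prob=0.05)
    detection = DetectionModel()
    acq = AcquisitionConfig(mean_track_length=100.0)
    total, bound = [], []
    for seed in seeds:
        diff_tracks, fluo_tracks, _ = simulate_experiment(
            spec, binding, detection, acq=acq, n_particles=n_particles, seed=seed
        )
        vol = 1e-6
        total.append(box_stats(bin_sizes(size_tracks(diff_tracks), vol)))
        bound.append(box_stats(bin_sizes(size_tracks(fluo_tracks), vol)))
    return total, bound


class TestPipelineClassification:
    def test_high_curvature_binder_called_smaller(self):
        total, bound = _experiment_modes("high_curvature", seeds=(1, 2, 3))
        assert classify_preference(total, bound).label == "smaller"

    def test_low_curvature_binder_called_larger(self):
        total, bound = _experiment_modes("low_curvature", seeds=(4, 5, 6))
        assert classify_preference(total, bound).label == "larger"


class TestVesiculationDoseResponse:
    def test_constant_distributions_give_constant_metric(self):
        d = make_dist({77.5: 2.0, 82.5: 5.0, 87.5: 1.0})
        res = vesiculation_dose_response({0.0: d, 1.0: d, 2.0: d})
        assert res.metric == (5.0, 5.0, 5.0)
        assert res.doses == (0.0, 1.0, 2.0)

    def test_baseline_metric_is_marker_bin_lookup(self):
        base = make_dist({77.5: 2.0, 82.5: 5.0, 87.5: 1.0})
        high = make_dist({77.5: 4.0, 82.5: 9.0, 87.5: 2.0})
        res = vesiculation_dose_response({0.0: base, 4.0: high})
        assert res.metric[0] == 5.0

    def test_missing_baseline_rejected(self):
        d = make_dist({82.5: 1.0})
        with pytest.raises(ValueError, match="dose-0"):
            vesiculation_dose_response({1.0: d, 2.0: d})

    def test_stronger_vesiculator_scores_higher(self):
        rng = np.random.default_rng(31)
        parents = sample_population(PopulationSpec(), 2000, seed=rng)
        sample = SimulatedSample(parents, np.ones(parents.size, dtype=bool), volume=1e-5)

        def titrate(max_fraction, seed):
            dists = {}
            for dose in (0.0, 1.0, 4.0):
                model = VesiculationModel(dose=dose, max_fraction=max_fraction)
                out = vesiculate(sample, model, seed=seed)
                dists[dose] = bin_diameters(out.diameters, out.volume)
            return vesiculation_dose_response(dists)

        strong = titrate(0.8, seed=1)  # ENTH-like
        weak = titrate(0.2, seed=1)  # Hip1R-like
        assert strong.metric_at(4.0) > weak.metric_at(4.0)
        assert strong.mean_size[-1] < strong.mean_size[0]  # vesiculation shrinks the mean


class TestCompareEfficiency:
    def _replicates(self, max_fraction, seeds, dose=4.0):
        out = []
        for seed in seeds:
            parents = sample_population(PopulationSpec(), 1500, seed=seed)
            sample = SimulatedSample(parents, np.ones(parents.size, dtype=bool), volume=1e-5)
            dists = {}
            for d in (0.0, dose):
                model = VesiculationModel(dose=d, max_fraction=max_fraction)
                v = vesiculate(sample, model, seed=seed + 1000)
                dists[d] = bin_diameters(v.diameters, v.volume)
            out.append(vesiculation_dose_response(dists))
        return out

    def test_identical_replicates_give_zero_difference(self):
        reps = self._replicates(0.5, seeds=(1, 2, 3))
        diff, p = compare_efficiency(reps, reps, dose=4.0)
        assert diff == 0.0 and p == 1.0

    def test_stronger_vs_weaker_significant(self):
        strong = self._replicates(0.8, seeds=(1, 2, 3, 4, 5))
        weak = self._replicates(0.2, seeds=(6, 7, 8, 9, 10))
        diff, p = compare_efficiency(strong, weak, dose=4.0)
        assert diff > 0
        assert p < 0.05

    def test_swapping_negates_difference(self):
        a = self._replicates(0.8, seeds=(1, 2, 3))
        b = self._replicates(0.2, seeds=(4, 5, 6))
        d_ab, p_ab = compare_efficiency(a, b, dose=4.0)
        d_ba, p_ba = compare_efficiency(b, a, dose=4.0)
        assert d_ab == pytest.approx(-d_ba)
        assert p_ab == pytest.approx(p_ba)

    def test_off_grid_dose_rejected(self):
        reps = self._replicates(0.5, seeds=(1, 2, 3))
        with pytest.raises(KeyError):
            compare_efficiency(reps, reps, dose=2.0)
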
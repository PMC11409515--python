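import numpy as np
import pandas as pd
import pytest

from relmap import (
    ProbeType,
    SmoothingParams,
    ValidationError,
    dynamic_threshold,
    find_critical_point,
    fit_smoothed_curve,
    flag_unreliable,
)
from relmap.threshold import SmoothedCurve


def mi_table(values):
    return pd.DataFrame(
        {
            "probe_id": [f"cg{i:07d}" for i in range(len(values))],
            "infinium_type": "II",
            "mi": np.asarray(values, dtype=float),
            "n_samples_used": 10,
        }
    )


class TestFitSmoothedCurve:
    def test_constant_input_gives_flat_curve(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 2, 300)
        curve = fit_smoothed_curve(x, np.full(300, 0.25))
        np.testing.assert_allclose(curve.values, 0.25, atol=1e-8)

    def test_noiseless_exponential_recovered_within_one_percent(self):
        rng = np.random.default_rng(1)
        x = np.sort(rng.uniform(0, 3, 5000))
        a, s, c = 0.03, 0.6, 0.002
        y = a * np.exp(-x / s) + c
        curve = fit_smoothed_curve(x, y, SmoothingParams(upper_quantile=1.0))
        truth = a * np.exp(-curve.mi_grid / s) + c
        interior = slice(len(curve.mi_grid) // 20, -len(curve.mi_grid) // 20)
        assert np.abs(curve.values - truth)[interior].max() < 0.01 * a

    def test_duplicating_every_row_leaves_fit_unchanged(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 2, 400)
        y = 0.02 * np.exp(-x) + 0.001 * rng.standard_normal(400)
        c1 = fit_smoothed_curve(x, y)
        c2 = fit_smoothed_curve(np.r_[x, x], np.r_[y, y])
        np.testing.assert_allclose(c1.values, c2.values, rtol=1e-9)

    def test_constant_mi_rejected(self):
        with pytest.raises(ValidationError):
            fit_smoothed_curve(np.ones(100), np.linspace(0, 1, 100))

    def test_too_few_probes_rejected(self):
        with pytest.raises(ValidationError):
            fit_smoothed_curve(np.linspace(0, 1, 30), np.zeros(30))

    def test_deterministic_given_params(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 2, 500)
        y = np.exp(-x) + 0.01 * rng.standard_normal(500)
        c1 = fit_smoothed_curve(x, y)
        c2 = fit_smoothed_curve(x, y)
        np.testing.assert_array_equal(c1.values, c2.values)


class TestCriticalPoint:
    def test_flat_curve_has_no_critical_point(self):
        curve = SmoothedCurve(np.linspace(0, 1, 64), np.zeros(64), SmoothingParams(), 1.0)
        with pytest.raises(ValidationError, match="no critical point"):
            find_critical_point(curve)

    def test_exponential_curvature_peaks_early_in_searched_region(self):
        # a convex decay's curvature is largest where the drop is steepest;
        # natural boundary conditions push the finite-difference argmax a
        # little inside the searched region, still well left of centre.
        rng = np.random.default_rng(4)
        x = np.sort(rng.uniform(0, 3, 5000))
        y = 0.03 * np.exp(-x / 0.5) + 0.002
        curve = fit_smoothed_curve(x, y, SmoothingParams(upper_quantile=1.0))
        crit_mi, crit_val = find_critical_point(curve)
        span = curve.mi_grid[-1] - curve.mi_grid[0]
        assert crit_mi < curve.mi_grid[0] + 0.25 * span
        assert crit_val == pytest.approx(0.03 * np.exp(-crit_mi / 0.5) + 0.002, rel=0.15)

    def test_piecewise_kink_located_near_break(self):
        # steep linear drop until t, then constant: curvature concentrates
        # at the kink after smoothing.
        rng = np.random.default_rng(5)
        x = np.sort(rng.uniform(0, 3, 6000))
        t = 0.9
        y = np.where(x < t, 0.05 * (t - x) / t + 0.005, 0.005)
        curve = fit_smoothed_curve(x, y, SmoothingParams(upper_quantile=1.0))
        crit_mi, _ = find_critical_point(curve)
        knot_spacing = (curve.mi_grid[-1] - curve.mi_grid[0]) / (
            curve.params.df - curve.params.degree
        )
        assert abs(crit_mi - t) < 2 * knot_spacing

    def test_requires_enough_grid_points(self):
        curve = SmoothedCurve(np.linspace(0, 1, 8), np.linspace(1, 0, 8), SmoothingParams(), 1.0)
        with pytest.raises(ValidationError):
            find_critical_point(curve)


class TestFlagging:
    def test_all_probes_above_threshold_gives_empty_set(self):
        assert flag_unreliable(mi_table([1.0, 2.0]), 0.5) == set()

    def test_only_probes_strictly_below_threshold_flagged(self):
        table = mi_table([0.1, 0.9, 1.5])
        assert flag_unreliable(table, 0.5) == {"cg0000000"}

    def test_exact_threshold_probe_not_flagged(self):
        table = mi_table([0.5, 0.4])
        assert flag_unreliable(table, 0.5) == {"cg0000001"}

    def test_monotone_flag_property(self):
        rng = np.random.default_rng(6)
        table = mi_table(rng.uniform(0, 3, 200))
        flagged = flag_unreliable(table, 1.0)
        flagged_mi = table.loc[table.probe_id.isin(flagged), "mi"]
        unflagged_mi = table.loc[~table.probe_id.isin(flagged), "mi"]
        assert flagged_mi.max() < unflagged_mi.min()


@pytest.fixture(scope="module")
def scored():
    # synthetic scatter: steep unreliability decay that flattens
    rng = np.random.default_rng(7)
    mi = np.sort(rng.uniform(0.02, 3, 4000))
    unrel = 0.03 / (1 + (mi / 0.25) ** 2) + 0.0005 * rng.standard_normal(4000)
    table = mi_table(mi)
    unrel_table = table[["probe_id"]].assign(unreliability=np.clip(unrel, 0, None))
    return table, unrel_table


class TestDynamicThreshold:
    def test_threshold_flags_low_mi_probes(self, scored):
        table, unrel_table = scored
        res = dynamic_threshold(table, unrel_table, ProbeType.II)
        assert res.critical_mi > table["mi"].min()
        assert res.flagged_probes == flag_unreliable(table, res.critical_mi)

    def test_flag_by_unreliability_option(self, scored):
        table, unrel_table = scored
        res = dynamic_threshold(table, unrel_table, ProbeType.II, flag_by="unreliability")
        merged = table.merge(unrel_table, on="probe_id")
        expected = set(merged.loc[merged.unreliability > res.critical_unreliability, "probe_id"])
        assert res.flagged_probes == expected

    def test_stability_under_extreme_mi_contamination(self, scored):
        table, unrel_table = scored
        base = dynamic_threshold(table, unrel_table, ProbeType.II)
        n_extra = len(table) // 100
        extra_mi = mi_table(np.full(n_extra, 6.0))
        extra_mi["probe_id"] = [f"ex{i}" for i in range(n_extra)]
        extra_un = extra_mi[["probe_id"]].assign(unreliability=0.0005)
        table2 = pd.concat([table, extra_mi], ignore_index=True)
        unrel2 = pd.concat([unrel_table, extra_un], ignore_index=True)
        res = dynamic_threshold(table2, unrel2, ProbeType.II)
        grid_step = np.diff(base.curve.mi_grid[:2])[0]
        assert abs(res.critical_mi - base.critical_mi) < grid_step
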
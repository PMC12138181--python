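import numpy as np
import pytest

import herbchron as hc
from herbchron.richards import (
    RichardsParams,
    assign_cohort,
    compare_cohorts,
    derived_quantities,
    fit_richards,
    richards_value,
    tradeoff_correlations,
)
from herbchron.ring_io import GrowthTrajectory


def make_trajectory(params, ages=None, pid="T1"):
    if ages is None:
        ages = np.arange(1, 26, dtype=float)
    return GrowthTrajectory(pid, ages, richards_value(params, ages))


class TestRichardsValue:
    def test_logistic_half_asymptote_at_inflection(self):
        p = RichardsParams(A=10.0, r=0.5, delta=1.0, t_star=8.0)
        assert richards_value(p, 8.0) == pytest.approx(5.0)

    def test_direct_formula_evaluation(self):
        p = RichardsParams(A=8.0, r=0.4, delta=2.0, t_star=10.0)
        assert richards_value(p, 10.0) == pytest.approx(8.0 * 1.5**-2, abs=1e-12)

    def test_approaches_asymptote(self):
        p = RichardsParams(A=10.0, r=0.5, delta=1.0, t_star=8.0)
        t = p.t_star + 50.0 / p.r
        assert abs(richards_value(p, t) - p.A) / p.A < 1e-3

    def test_monotone_and_bounded(self):
        p = RichardsParams(A=6.0, r=0.3, delta=2.5, t_star=12.0)
        t = np.linspace(0, 100, 500)
        d = richards_value(p, t)
        assert np.all(np.diff(d) > 0)
        assert np.all(d < p.A)

    def test_delta_1_is_exact_logistic(self):
        p = RichardsParams(A=7.0, r=0.6, delta=1.0, t_star=9.0)
        t = np.linspace(0, 40, 100)
        logistic = p.A / (1.0 + np.exp(-p.r * (t - p.t_star)))
        np.testing.assert_allclose(richards_value(p, t), logistic, atol=1e-12)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            RichardsParams(A=-1.0, r=0.5, delta=1.0, t_star=5.0)


class TestDerivedQuantities:
    def test_logistic_max_growth_rate(self):
        p = RichardsParams(A=10.0, r=0.5, delta=1.0, t_star=8.0)
        dq = derived_quantities(p)
        assert dq["max_agr"] == pytest.approx(10.0 * 0.5 * 2.0**-2)
        assert dq["d_at_inflection"] / p.A == pytest.approx(0.5)

    def test_inflection_size_below_asymptote(self):
        p = RichardsParams(A=5.0, r=0.4, delta=3.0, t_star=10.0)
        dq = derived_quantities(p)
        assert 0.0 < dq["d_at_inflection"] < p.A

    def test_discrete_max_increment_age_near_t_star(self):
        for ts in (6.0, 9.0, 13.0):
            p = RichardsParams(A=6.0, r=0.5, delta=1.0, t_star=ts)
            dq = derived_quantities(p)
            assert abs(dq["empirical_max_agr_age"] - ts) < 1.0


class TestFitRichards:
    def test_noise_free_recovery_within_half_percent(self):
        true = RichardsParams(A=6.0, r=0.5, delta=1.0, t_star=8.0)
        fit = fit_richards(make_trajectory(true))
        assert fit.converged
        for name in ("A", "r", "delta", "t_star"):
            est, tv = getattr(fit.params, name), getattr(true, name)
            assert abs(est - tv) / tv < 0.005, name

    def test_scale_equivariance(self):
        true = RichardsParams(A=6.0, r=0.5, delta=1.0, t_star=8.0)
        traj = make_trajectory(true)
        s = 7.3
        scaled = GrowthTrajectory("T2", traj.ages, s * traj.basal_area_mm2)
        f1, f2 = fit_richards(traj), fit_richards(scaled)
        assert f2.params.A == pytest.approx(s * f1.params.A, rel=1e-6)
        assert f2.max_agr == pytest.approx(s * f1.max_agr, rel=1e-6)
        for name in ("r", "delta", "t_star"):
            assert getattr(f2.params, name) == pytest.approx(getattr(f1.params, name), rel=1e-6)

    def test_rss_not_worse_than_initialisation(self):
        rng = np.random.default_rng(8)
        true = RichardsParams(A=4.0, r=0.35, delta=1.5, t_star=9.0)
        ages = np.arange(1, 21, dtype=float)
        clean = richards_value(true, ages)
        incr = np.diff(np.concatenate([[0.0], clean]))
        noisy = np.cumsum(incr * np.exp(rng.normal(0, 0.05, incr.size)))
        traj = GrowthTrajectory("N1", ages, noisy)
        fit = fit_richards(traj)
        from herbchron.richards import _initial_guess

        p0 = _initial_guess(ages, noisy)
        p0_params = RichardsParams(*np.clip(p0, [1e-9, 1e-9, 0.05, 1e-9], None))
        rss0 = float(np.sum((richards_value(p0_params, ages) - noisy) ** 2))
        assert fit.rss <= rss0 + 1e-12

    def test_short_trajectory_rejected(self):
        with pytest.raises(ValueError):
            fit_richards(make_trajectory(RichardsParams(5, 0.5, 1, 5), ages=np.arange(1, 5.0)))


@pytest.mark.parametrize(
    "year,expected", [(1999, "cold"), (2005, "cold"), (2006, "warm"), (2010, "warm"), (1988, "unassigned")]
)
def test_assign_cohort_defaults(year, expected):
    assert assign_cohort(year) == expected


class TestCompareCohorts:
    def test_recovers_planted_r_shift(self):
        cfg = hc.SyntheticConfig(seed=99, n_cold=50, n_warm=50)
        trajs, truth = hc.simulate_richards_cohorts(cfg)
        fits = [fit_richards(t) for t in trajs.values()]
        labels = {pid: rec["cohort"] for pid, rec in truth.items()}
        comp = compare_cohorts(fits, labels)
        row = comp.table.loc["r"]
        assert row["pct_diff"] == pytest.approx(35.3, abs=10)
        assert row["p"] < 0.05
        # warm plants decelerate earlier: negative t* shift
        assert comp.table.loc["t_star", "pct_diff"] < 0

    def test_truncation_control_stable_when_t_star_early(self):
        """Noise-free cold trajectories with t* < 9 refit unchanged at max age 11."""
        rng = np.random.default_rng(4)
        fits, labels, trajs = [], {}, {}
        for i in range(6):
            true = RichardsParams(A=4.0 + 0.2 * i, r=0.45, delta=1.0, t_star=6.0 + 0.3 * i)
            traj = make_trajectory(true, ages=np.arange(1, 26, dtype=float), pid=f"c{i}")
            trajs[f"c{i}"] = traj
            labels[f"c{i}"] = "cold"
            fits.append(fit_richards(traj))
        for i in range(6):
            true = RichardsParams(A=3.0, r=0.6, delta=1.0, t_star=5.0 + 0.1 * i)
            traj = make_trajectory(true, ages=np.arange(1, 12, dtype=float), pid=f"w{i}")
            trajs[f"w{i}"] = traj
            labels[f"w{i}"] = "warm"
            fits.append(fit_richards(traj))
        full = compare_cohorts(fits, labels)
        trunc = compare_cohorts(fits, labels, trajectories=trajs, truncate_to=11)
        for name in ("A", "r", "t_star"):
            assert trunc.table.loc[name, "mean_cold"] == pytest.approx(
                full.table.loc[name, "mean_cold"], rel=0.05
            )
        assert trunc.truncated_to == 11

    def test_insufficient_cohort_rejected(self):
        true = RichardsParams(A=4.0, r=0.4, delta=1.0, t_star=7.0)
        fits = [fit_richards(make_trajectory(true, pid=f"p{i}")) for i in range(4)]
        labels = {"p0": "cold", "p1": "cold", "p2": "warm", "p3": "warm"}
        with pytest.raises(ValueError, match="3"):
            compare_cohorts(fits, labels)

    def test_mannwhitney_option(self):
        cfg = hc.SyntheticConfig(seed=12, n_cold=15, n_warm=15)
        trajs, truth = hc.simulate_richards_cohorts(cfg)
        fits = [fit_richards(t) for t in trajs.values()]
        labels = {pid: rec["cohort"] for pid, rec in truth.items()}
        comp = compare_cohorts(fits, labels, test="mannwhitney")
        assert (comp.table["p"] <= 1.0).all()


class TestTradeoffs:
    def test_recovers_built_in_negative_r_tstar_correlation(self):
        cfg = hc.SyntheticConfig(seed=5, n_cold=75, n_warm=75, r_tstar_corr=-0.6,
                                 warm_r_factor=1.0, warm_t_star_shift=0.0, warm_A_factor=1.0,
                                 warm_max_age=29)  # observe past the inflection
        trajs, _ = hc.simulate_richards_cohorts(cfg)
        fits = [fit_richards(t) for t in trajs.values()]
        tab = tradeoff_correlations(fits)
        assert tab.loc["r~t_star", "r"] == pytest.approx(-0.6, abs=0.15)

    def test_independent_parameters_show_no_tradeoff(self):
        cfg = hc.SyntheticConfig(seed=6, n_cold=75, n_warm=75, r_tstar_corr=0.0,
                                 warm_r_factor=1.0, warm_t_star_shift=0.0, warm_A_factor=1.0,
                                 warm_max_age=29)
        trajs, _ = hc.simulate_richards_cohorts(cfg)
        fits = [fit_richards(t) for t in trajs.values()]
        tab = tradeoff_correlations(fits)
        assert abs(tab.loc["r~t_star", "r"]) < 0.2

    def test_fewer_than_ten_fits_rejected(self):
        true = RichardsParams(A=4.0, r=0.4, delta=1.0, t_star=7.0)
        fits = [fit_richards(make_trajectory(true, pid=f"p{i}")) for i in range(5)]
        with pytest.raises(ValueError, match="10"):
            tradeoff_correlations(fits)
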
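"""Product-limit estimation, medians, Monte Carlo CIs, competing risks."""

import numpy as np
import pandas as pd
import pytest

import artdating as ad
from artdating.survival import (
    MedianEstimate,
    _interp_median,
    aalen_johansen,
    km_fit,
    mc_median_ci,
    mc_median_difference_ci,
    strategy_compare,
    survival_median,
)


def test_km_no_censoring_is_empirical_survival():
    c = km_fit([5, 8, 12], [True, True, True])
    np.testing.assert_allclose(c.S, [2 / 3, 1 / 3, 0.0])
    np.testing.assert_array_equal(c.n_at_risk, [3, 2, 1])


def test_km_hand_product_limit_with_censoring():
    c = km_fit([5, 8, 12], [True, False, True])
    np.testing.assert_allclose(c.S, [2 / 3, 2 / 3, 0.0])
    # Greenwood on log S: 1/(3*2) at t=5; t=8 censoring adds nothing
    np.testing.assert_allclose(c.var_logS[:2], [1 / 6, 1 / 6])
    assert survival_median(c, interpolate=False) == 12


def test_km_tie_convention_events_before_censorings():
    # the record censored at t=8 is still at risk for the t=8 event
    c = km_fit([5, 8, 8, 10], [True, True, False, True])
    row = list(c.times).index(8)
    assert c.n_at_risk[row] == 3
    np.testing.assert_allclose(c.S[row], (3 / 4) * (2 / 3))


def test_km_input_validation():
    with pytest.raises(ValueError):
        km_fit([1, 2], [False, False])  # no events
    with pytest.raises(ValueError):
        km_fit([-1, 2], [True, True])
    with pytest.raises(ValueError):
        km_fit([], [])


def test_km_greenwood_against_naive_oracle():
    """S(t) matches lifelines and var(log S) matches a brute-force
    accumulation, to 1e-12, on fuzzed tied instances."""
    lifelines = pytest.importorskip("lifelines")
    rng = np.random.default_rng(4)
    for _ in range(25):
        n = int(rng.integers(5, 200))
        t = rng.integers(1, 25, size=n).astype(float)
        e = rng.random(n) < 0.6
        if not e.any():
            continue
        c = km_fit(t, e)
        kmf = lifelines.KaplanMeierFitter().fit(t, e)
        np.testing.assert_allclose(
            c.S, kmf.survival_function_at_times(c.times).to_numpy(), atol=1e-12
        )
        # independent naive Greenwood accumulation
        acc, expect = 0.0, []
        for u in c.times:
            ni = int((t >= u).sum())
            di = int(((t == u) & e).sum())
            if ni > di:
                acc += di / (ni * (ni - di))
            elif di:
                acc = np.inf
            expect.append(acc)
        np.testing.assert_allclose(c.var_logS, expect, atol=1e-12)


def test_cumulative_birth_distribution_complement():
    c = km_fit([5, 8, 12], [True, False, True])
    F = ad.cumulative_birth_distribution(c)
    np.testing.assert_allclose(F["F"].to_numpy() + c.S, 1.0)
    assert F["F"].iloc[-1] == 1.0


def test_step_median_no_censoring_odd_n():
    c = km_fit([7, 3, 11], [True] * 3)
    assert survival_median(c, interpolate=False) == 7.0


def test_interpolated_median_day_grain():
    # S: 1 -> 0.524 at 282, -> 0.476 at 283: crossing at day 283's center
    m = _interp_median(np.array([282.0, 283.0]), np.array([0.524, 0.476]))
    assert m == pytest.approx(283.0, abs=1e-9)


def test_median_undefined_under_heavy_censoring():
    c = km_fit([5, 6, 7, 8], [True, False, False, False])
    with pytest.raises(ValueError, match="undefined"):
        survival_median(c)


def test_mc_ci_zero_variance_collapses():
    c = km_fit(np.arange(1, 42, dtype=float), np.ones(41, bool))
    forced = ad.SurvivalCurve(
        times=c.times, n_at_risk=c.n_at_risk, n_events=c.n_events,
        n_censored=c.n_censored, S=c.S, var_logS=np.zeros_like(c.var_logS),
        n_total=c.n_total,
    )
    est = mc_median_ci(forced, n_sim=500, seed=0)
    assert est.ci[0] == pytest.approx(est.median)
    assert est.ci[1] == pytest.approx(est.median)


def test_mc_ci_brackets_point_and_is_seeded(big_spont):
    curve = strategy_compare(big_spont, "censor")
    a = mc_median_ci(curve, n_sim=500, seed=3)
    b = mc_median_ci(curve, n_sim=500, seed=3)
    assert a == b
    assert a.ci[0] <= a.median <= a.ci[1]


def test_mc_ci_comparable_to_bootstrap(big_spont):
    """MC half-width within +/-30% of a nonparametric bootstrap of the
    KM median on the same data."""
    df = big_spont.sample(4000, random_state=1)
    times = df.ga_us_birth_days.to_numpy(float)
    events = (df.onset_type == "spontaneous").to_numpy()
    est = mc_median_ci(km_fit(times, events), n_sim=1500, seed=5)
    rng = np.random.default_rng(6)
    meds = []
    for _ in range(300):
        idx = rng.integers(0, len(times), len(times))
        meds.append(survival_median(km_fit(times[idx], events[idx])))
    blo, bhi = np.quantile(meds, [0.025, 0.975])
    mc_w, bs_w = est.ci[1] - est.ci[0], bhi - blo
    assert 0.7 * bs_w <= mc_w <= 1.3 * bs_w


def test_median_difference_identical_and_antisymmetric(big_spont):
    curve = strategy_compare(big_spont, "censor")
    same = mc_median_difference_ci(curve, curve, n_sim=300, seed=1)
    assert same.median == 0.0
    assert same.ci[0] <= 0.0 <= same.ci[1]

    other = strategy_compare(big_spont.sample(20_000, random_state=2), "censor")
    ab = mc_median_difference_ci(curve, other, n_sim=400, seed=7)
    ba = mc_median_difference_ci(other, curve, n_sim=400, seed=7)
    assert ab.median == -ba.median
    assert ab.ci[0] == pytest.approx(-ba.ci[1], abs=1e-9)
    assert ab.ci[1] == pytest.approx(-ba.ci[0], abs=1e-9)


def test_median_estimate_rejects_nonbracketing_ci():
    with pytest.raises(ValueError):
        MedianEstimate(median=5.0, ci=(6.0, 7.0), method="bootstrap")


def test_strategies_coincide_without_censoring():
    df = pd.DataFrame(
        {
            "ga_us_birth_days": [270, 280, 283, 290],
            "onset_type": "spontaneous",
            "conception_mode": "spontaneous",
        }
    )
    medians = {
        s: survival_median(strategy_compare(df, s), interpolate=False)
        for s in ("censor", "exclude", "as_event")
    }
    assert len(set(medians.values())) == 1


def test_unknown_strategy_rejected(small_cohort):
    with pytest.raises(ValueError):
        strategy_compare(small_cohort, "drop")


def test_aalen_johansen_hand_example():
    t = np.array([280.0, 270.0, 285.0, 290.0])
    cause = np.array(
        ["spontaneous_onset", "preeclampsia_delivery", "censored", "spontaneous_onset"],
        dtype=object,
    )
    inc = aalen_johansen(t, cause)
    frame = inc.to_frame().set_index("t")
    assert frame.loc[270.0, "cif_preeclampsia_delivery"] == pytest.approx(0.25)
    assert frame.loc[280.0, "cif_spontaneous_onset"] == pytest.approx(0.25)
    # increment 1/2 at t=290 on top of 1/4
    assert frame.loc[290.0, "cif_spontaneous_onset"] == pytest.approx(0.75)
    total = inc.overall_survival + sum(inc.cif.values())
    np.testing.assert_allclose(total, 1.0, atol=1e-12)


def test_aalen_johansen_single_cause_reduces_to_km():
    t = np.array([3.0, 5.0, 5.0, 9.0, 11.0])
    cause = np.array(["onset", "onset", "censored", "onset", "censored"], dtype=object)
    inc = aalen_johansen(t, cause)
    c = km_fit(t, cause != "censored")
    np.testing.assert_allclose(inc.cif["onset"], 1.0 - c.S, atol=1e-12)


def test_aalen_johansen_against_lifelines():
    # untied continuous times: lifelines jitters ties, which would break
    # an exact comparison
    lifelines = pytest.importorskip("lifelines")
    rng = np.random.default_rng(12)
    times = np.sort(rng.normal(283, 9, size=150))
    causes = rng.choice(
        np.array(["spontaneous_onset", "preeclampsia_delivery", "censored"], dtype=object),
        size=150,
        p=[0.6, 0.15, 0.25],
    )
    inc = aalen_johansen(times, causes)
    ev = np.where(causes == "spontaneous_onset", 1, np.where(causes == "censored", 0, 2))
    ajf = lifelines.AalenJohansenFitter(calculate_variance=False).fit(
        times, ev, event_of_interest=1
    )
    theirs = ajf.cumulative_density_.iloc[:, 0]
    ours = pd.Series(inc.cif["spontaneous_onset"], index=inc.times)
    common = [t for t in inc.times if t in theirs.index]
    np.testing.assert_allclose(ours.loc[common], theirs.loc[common], atol=1e-10)


def test_aalen_johansen_requires_events():
    with pytest.raises(ValueError):
        aalen_johansen(np.array([1.0, 2.0]), np.array(["censored", "censored"], dtype=object))


def test_remaining_duration_by_culture(small_cohort):
    out = ad.remaining_duration_by_culture(small_cohort, n_sim=300, seed=1)
    out = out.set_index(["conception_mode", "culture_days"])
    # one extra culture day shortens transfer-to-birth accordingly
    assert (
        out.loc[("fresh_et", 2), "median_days"] > out.loc[("fresh_et", 5), "median_days"]
    )
    # frozen ET runs ~3 days longer than fresh at a fixed culture day
    gap = out.loc[("frozen_et", 5), "median_days"] - out.loc[("fresh_et", 5), "median_days"]
    assert 1.0 < gap < 5.0
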
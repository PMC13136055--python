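"""Synthetic birth-registry cohorts.

Every downstream stage of the analysis (exclusions, dating agreement,
censoring-aware birth distributions) is exercised against cohorts drawn
here, since the real registry data sit behind an application portal.

The generative model, per pregnancy record:

1. follicular phase ``F`` ~ shifted lognormal (median 15 d, right-skewed);
   oocyte fertilization falls on LMP day ``F``;
2. ART records draw embryo-culture days ``c`` from the group mixture over
   {2, 3, 5}; the (thaw-)transfer falls on LMP day ``F + c``;
3. latent spontaneous-onset GA ``T`` ~ left-skewed skew-normal with the
   group median (283 d spontaneous/fresh ET, 286 d frozen ET);
4. a potential intervention GA ``I`` ~ Normal(276, 9) is realized with a
   probability tuned (on the rounded-day scale) so that the expected
   nonspontaneous fraction hits the group target; the birth occurs at
   ``min(T, I)`` and is right-censored when the intervention wins;
5. the registry records ultrasound GA at birth as the true GA plus
   rounded Gaussian error, truncated at 154 days (22 weeks).

All GA values are rounded to whole days, the registry's granularity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .params import (
    FRESH_ET,
    FROZEN_ET,
    GROUPS,
    MIN_GA_DAYS,
    SPONTANEOUS,
    GeneratorParams,
)

__all__ = ["simulate_cohort", "onset_distribution", "realization_probability"]

_EPOCH = np.datetime64("2015-01-01")
_LMP_SPAN_DAYS = 2200  # births spread over a 2015-2021-style window

# split of nonspontaneous births by onset type; the emergency pre-labor
# cesarean share is small and fixed
_EMERGENCY_CS_SHARE = 0.02
_INDUCED_SHARE = 0.74
_ELECTIVE_CS_SHARE = 0.24

_ID_PREFIX = {SPONTANEOUS: "sp", FRESH_ET: "fr", FROZEN_ET: "fz"}


def onset_distribution(params: GeneratorParams, group: str):
    """Frozen scipy distribution of the latent onset GA for one group.

    Skew-normal parameterized directly by its median: the location is
    solved from the shape and scale so that ``ppf(0.5)`` equals
    ``onset_median_days[group]`` exactly.
    """
    a = params.onset_skew
    omega = params.onset_spread_days[group]
    z50 = stats.skewnorm.ppf(0.5, a)
    xi = params.onset_median_days[group] - omega * z50
    return stats.skewnorm(a, loc=xi, scale=omega)


def _follicular_lognorm(params: GeneratorParams):
    """Shifted lognormal follicular phase: returns (shift, mu, sigma)."""
    sigma = params.follicular_skew
    z95 = stats.norm.ppf(0.95)
    scale = params.follicular_spread_days / (2.0 * np.sinh(z95 * sigma))
    shift = params.follicular_median_days - scale
    return shift, np.log(scale), sigma


def realization_probability(params: GeneratorParams, group: str) -> float:
    """Bernoulli probability that a potential intervention is realized.

    Tuned so that ``P(realized) * P(I < T)`` on the rounded-day scale
    equals the group's censor target.  The competition probability
    ``P(round(I) < round(T))`` is computed by exact summation over the
    integer-day grid, so the tuning does not depend on the seed.
    """
    target = params.censor_target_fraction[group]
    if target == 0.0:
        return 0.0
    onset = onset_distribution(params, group)
    days = np.arange(100, 421)
    p_onset_day = onset.cdf(days + 0.5) - onset.cdf(days - 0.5)
    # P(round(I) <= d - 1) = P(I < d - 0.5)
    p_interv_before = stats.norm.cdf(
        days - 0.5, params.intervention_mean_days, params.intervention_sd_days
    )
    p_compete = float(np.sum(p_onset_day * p_interv_before))
    p = target / p_compete
    if p > 1.0:
        raise ValueError(
            f"censor target {target} for group {group!r} is unattainable: "
            f"P(intervention precedes onset) is only {p_compete:.3f}"
        )
    return p


def simulate_cohort(params: GeneratorParams) -> pd.DataFrame:
    """Draw a full synthetic cohort as one record-per-row DataFrame.

    Columns follow the registry schema plus two generator-truth columns
    (``latent_onset_ga_days``, ``latent_intervention_ga_days``) that are
    absent from analysis input.  Identical params give a byte-identical
    frame.
    """
    params.validate()
    seeds = np.random.SeedSequence(params.seed).spawn(3)
    frames = []
    sizes = {SPONTANEOUS: params.n_spont, FRESH_ET: params.n_fresh, FROZEN_ET: params.n_frozen}
    for group, seed in zip(GROUPS, seeds):
        n = sizes[group]
        if n:
            frames.append(_simulate_group(params, group, n, np.random.default_rng(seed)))
    if not frames:
        return _empty_cohort()
    out = pd.concat(frames, ignore_index=True)
    return out


def _simulate_group(
    params: GeneratorParams, group: str, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    is_art = group != SPONTANEOUS
    shift, mu, sigma = _follicular_lognorm(params)
    follicular = np.rint(shift + rng.lognormal(mu, sigma, size=n)).astype(np.int64)
    follicular = np.maximum(follicular, 5)

    if is_art:
        mix = (
            params.culture_day_mix_fresh if group == FRESH_ET else params.culture_day_mix_frozen
        )
        days = np.array(sorted(mix), dtype=np.int64)
        w = np.array([mix[d] for d in days], dtype=float)
        culture = rng.choice(days, size=n, p=w / w.sum())
    else:
        culture = np.zeros(n, dtype=np.int64)

    onset = onset_distribution(params, group)
    t_cont = onset.rvs(size=n, random_state=rng)
    t_latent = np.rint(t_cont).astype(np.int64)

    # two-part intervention process: candidate realization x candidate time
    p_base = realization_probability(params, group)
    if params.informative_censoring:
        # late latent onsets attract interventions (e.g. post-term induction)
        med = params.onset_median_days[group]
        p_real = np.clip(p_base * 2.0 * expit((t_cont - med) / 4.0), 0.0, 1.0)
    else:
        p_real = np.full(n, p_base)
    realized = rng.random(n) < p_real
    i_latent = np.rint(
        rng.normal(params.intervention_mean_days, params.intervention_sd_days, size=n)
    ).astype(np.int64)

    censored = realized & (i_latent < t_latent)
    birth_ga = np.where(censored, i_latent, t_latent)
    floor_ga = np.maximum(MIN_GA_DAYS, follicular + culture + 1)
    birth_ga = np.maximum(birth_ga, floor_ga)

    if params.us_error_sd_days > 0:
        err = np.rint(rng.normal(0.0, params.us_error_sd_days, size=n)).astype(np.int64)
    else:
        err = np.zeros(n, dtype=np.int64)
    ga_us = np.maximum(birth_ga + err, MIN_GA_DAYS)

    onset_type = np.full(n, "spontaneous", dtype=object)
    n_cens = int(censored.sum())
    if n_cens:
        cats = rng.choice(
            np.array(["induced", "elective_cs", "emergency_cs_prelabor"], dtype=object),
            size=n_cens,
            p=[_INDUCED_SHARE, _ELECTIVE_CS_SHARE, _EMERGENCY_CS_SHARE],
        )
        onset_type[censored] = cats
    preeclampsia = np.zeros(n, dtype=bool)
    if n_cens:
        preeclampsia[censored] = rng.random(n_cens) < params.preeclampsia_fraction

    lmp_offset = rng.integers(0, _LMP_SPAN_DAYS, size=n)
    lmp = _EPOCH + lmp_offset.astype("timedelta64[D]")
    birth_date = lmp + birth_ga.astype("timedelta64[D]")
    if is_art:
        transfer_date = lmp + (follicular + culture).astype("timedelta64[D]")
        if group == FRESH_ET:
            fertilization_date = lmp + follicular.astype("timedelta64[D]")
        else:
            # frozen ET: the oocyte was fertilized and cryopreserved in an
            # earlier cycle; only culture_days (fertilization -> EC) is
            # reflected in the dating formula
            storage = rng.integers(30, 366, size=n)
            fertilization_date = transfer_date - (culture + storage).astype("timedelta64[D]")
    else:
        transfer_date = np.full(n, np.datetime64("NaT", "D"))
        fertilization_date = np.full(n, np.datetime64("NaT", "D"))

    age_loc = 33.5 if is_art else 30.5
    maternal_age = np.clip(rng.normal(age_loc, 4.6, size=n), 17.0, 48.0).round(1)
    parity = np.minimum(rng.poisson(0.4 if is_art else 0.9, size=n), 6)
    fetal_sex = np.where(rng.random(n) < 0.514, "male", "female")

    prefix = _ID_PREFIX[group]
    return pd.DataFrame(
        {
            "id": [f"{prefix}{i:07d}" for i in range(n)],
            "conception_mode": group,
            "lmp_date": pd.to_datetime(lmp),
            "fertilization_date": pd.to_datetime(fertilization_date),
            "culture_days": pd.array(culture if is_art else [pd.NA] * n, dtype="Int64"),
            "transfer_date": pd.to_datetime(transfer_date),
            "birth_date": pd.to_datetime(birth_date),
            "ga_us_birth_days": ga_us,
            "onset_type": onset_type,
            "preeclampsia": preeclampsia,
            "plurality": np.ones(n, dtype=np.int64),
            "perinatal_death": np.zeros(n, dtype=bool),
            "malformation": np.zeros(n, dtype=bool),
            "maternal_age_years": maternal_age,
            "parity": parity.astype(np.int64),
            "fetal_sex": fetal_sex,
            "latent_onset_ga_days": t_latent,
            "latent_intervention_ga_days": np.where(realized, i_latent.astype(float), np.nan),
        }
    )


def _empty_cohort() -> pd.DataFrame:
    cols = {
        "id": pd.Series(dtype=object),
        "conception_mode": pd.Series(dtype=object),
        "lmp_date": pd.Series(dtype="datetime64[ns]"),
        "fertilization_date": pd.Series(dtype="datetime64[ns]"),
        "culture_days": pd.Series(dtype="Int64"),
        "transfer_date": pd.Series(dtype="datetime64[ns]"),
        "birth_date": pd.Series(dtype="datetime64[ns]"),
        "ga_us_birth_days": pd.Series(dtype=np.int64),
        "onset_type": pd.Series(dtype=object),
        "preeclampsia": pd.Series(dtype=bool),
        "plurality": pd.Series(dtype=np.int64),
        "perinatal_death": pd.Series(dtype=bool),
        "malformation": pd.Series(dtype=bool),
        "maternal_age_years": pd.Series(dtype=float),
        "parity": pd.Series(dtype=np.int64),
        "fetal_sex": pd.Series(dtype=object),
        "latent_onset_ga_days": pd.Series(dtype=np.int64),
        "latent_intervention_ga_days": pd.Series(dtype=float),
    }
    return pd.DataFrame(cols)
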
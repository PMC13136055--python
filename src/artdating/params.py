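"""Parameterization of the synthetic birth-registry generator.

The generator emulates a national birth registry restricted to singleton
live births dated by a population-calibrated ultrasound model: per-group
onset-of-birth distributions, follicular-phase variation, integer-day
ultrasound dating error, embryo-culture-day mixtures for fresh and frozen
embryo transfer (ET), and an obstetric-intervention process that right-
censors the spontaneous onset of birth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

SPONTANEOUS = "spontaneous"
FRESH_ET = "fresh_et"
FROZEN_ET = "frozen_et"
GROUPS = (SPONTANEOUS, FRESH_ET, FROZEN_ET)

ONSET_TYPES = ("spontaneous", "induced", "elective_cs", "emergency_cs_prelabor")

#: days from the first day of the last menstrual period (LMP, day 0) at
#: which the estimated date of delivery falls on the calibrated scale
EDD_DAY = 283

#: minimum gestational age for registry inclusion: 22 completed weeks
MIN_GA_DAYS = 154

#: registry upper plausibility bound on ultrasound GA at birth
MAX_GA_DAYS = 310


@dataclass(frozen=True)
class GeneratorParams:
    """Full parameterization of the synthetic registry.

    Per-group fields are mappings keyed by conception mode
    (``spontaneous``, ``fresh_et``, ``frozen_et``).

    Parameters
    ----------
    n_spont, n_fresh, n_frozen
        Cohort sizes per conception group.
    onset_median_days
        Median of the latent spontaneous-onset GA distribution, in days
        from LMP day 0.  Frozen-ET pregnancies run about three days
        longer than fresh-ET or spontaneous ones.
    onset_spread_days
        Scale (skew-normal omega) of the onset distribution; the default
        puts the central 50% of onsets within about +/- 7 days of the
        median.
    onset_skew
        Skew-normal shape; negative values give the left-skewed onset
        distribution seen in birth registries (more early than late
        outliers).
    follicular_median_days
        Median days from LMP day 0 to ovulation/oocyte fertilization.
        15 days, not the customary 14, calibrates ART dating against the
        ultrasound scale.
    follicular_spread_days
        Span between the 5th and 95th percentile of the follicular phase
        (default 18 days: roughly 10 to 28 days).
    follicular_skew
        Log-scale standard deviation of the shifted-lognormal follicular
        phase; right-skewed, since long cycles are more common than very
        short ones.
    us_error_sd_days
        SD of the Gaussian ultrasound dating error, rounded to whole
        days in the registry record.  Zero is allowed for the error-free
        limit used in calibration identities.
    culture_day_mix_fresh, culture_day_mix_frozen
        Mixture weights over embryo-culture days {2, 3, 5} (days from
        oocyte fertilization to transfer, respectively cryopreservation).
    censor_target_fraction
        Per-group target fraction of nonspontaneous (induced / pre-labor
        cesarean) births, i.e. right-censored observations.
    informative_censoring
        When True, the intervention probability depends on the latent
        onset time, deliberately violating the independent-censoring
        assumption of the Kaplan-Meier estimator.
    preeclampsia_fraction
        Fraction of nonspontaneous births attributed to pre-eclampsia
        (the competing-event label).
    intervention_mean_days, intervention_sd_days
        Normal location/scale of the potential intervention GA; mass is
        concentrated between ~260 days and the onset of birth.
    seed
        RNG seed; identical params (including seed) give a
        byte-identical cohort.
    """

    n_spont: int = 0
    n_fresh: int = 0
    n_frozen: int = 0
    onset_median_days: Mapping[str, float] = field(
        default_factory=lambda: {SPONTANEOUS: 283.0, FRESH_ET: 283.0, FROZEN_ET: 286.0}
    )
    onset_spread_days: Mapping[str, float] = field(
        default_factory=lambda: {SPONTANEOUS: 16.58, FRESH_ET: 16.58, FROZEN_ET: 16.58}
    )
    onset_skew: float = -4.0
    follicular_median_days: float = 15.0
    follicular_spread_days: float = 18.0
    follicular_skew: float = 0.581
    us_error_sd_days: float = 2.5
    culture_day_mix_fresh: Mapping[int, float] = field(
        default_factory=lambda: {2: 922.0, 3: 500.0, 5: 569.0}
    )
    culture_day_mix_frozen: Mapping[int, float] = field(
        default_factory=lambda: {2: 245.0, 3: 117.0, 5: 1630.0}
    )
    censor_target_fraction: Mapping[str, float] = field(
        default_factory=lambda: {SPONTANEOUS: 0.307, FRESH_ET: 0.355, FROZEN_ET: 0.441}
    )
    informative_censoring: bool = False
    preeclampsia_fraction: float = 0.15
    intervention_mean_days: float = 276.0
    intervention_sd_days: float = 9.0
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_spont, self.n_fresh, self.n_frozen) < 0:
            raise ValueError("group counts must be >= 0")
        for g in GROUPS:
            f = self.censor_target_fraction[g]
            if not 0.0 <= f < 1.0:
                raise ValueError(f"censor_target_fraction[{g}]={f} outside [0, 1)")
            if self.onset_spread_days[g] <= 0:
                raise ValueError("onset_spread_days must be > 0")
        for mix in (self.culture_day_mix_fresh, self.culture_day_mix_frozen):
            w = list(mix.values())
            if any(x < 0 for x in w) or sum(w) <= 0:
                raise ValueError("culture-day mixture weights must be nonnegative and normalizable")
        if self.us_error_sd_days < 0:
            raise ValueError("us_error_sd_days must be >= 0")
        if self.follicular_spread_days <= 0 or self.follicular_skew <= 0:
            raise ValueError("follicular spread/skew must be > 0")
        if not 0.0 <= self.preeclampsia_fraction <= 1.0:
            raise ValueError("preeclampsia_fraction outside [0, 1]")
        if self.intervention_sd_days <= 0:
            raise ValueError("intervention_sd_days must be > 0")

    def replace(self, **kwargs) -> "GeneratorParams":
        return replace(self, **kwargs)


def default_params(**overrides) -> GeneratorParams:
    """Registry-calibrated defaults.

    Onset medians 283/283/286 days, 15-day median follicular phase,
    nonspontaneous fractions 30.7%/35.5%/44.1%, and culture-day mixes
    922:500:569 (fresh) and 245:117:1630 (frozen).  Deterministic.
    """
    p = GeneratorParams(**overrides)
    p.validate()
    return p
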
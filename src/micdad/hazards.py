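"""Age-dependent transition intensities of the illness-death model.

The illness-death model (IDM) has three states — Healthy, Diseased, Dead —
and three age-dependent transition rates: the mortality rate of the
non-diseased ``m0(a)``, the mortality rate of the diseased ``m1(a)`` and the
incidence rate ``i(a)``.  This module defines the parametric forms used
throughout the package and calibrates them, per setting, against published
summary quantities:

* ``m0`` is a Gompertz hazard, ``m0(a) = exp(log_level + slope * a)`` — the
  standard log-linear adult-mortality law, which also makes the downstream
  log-linear Poisson rate model correctly specified.
* the true mortality rate ratio ``MRR(a) = m1(a)/m0(a)`` is log-linear in
  age, ``exp(intercept - decay * a)``; with a Gompertz ``m0`` the diseased
  mortality ``m1 = m0 * MRR`` is again Gompertz.
* the incidence ``i(a)`` is zero below a disease-specific onset age and
  log-linear above it; its two parameters are calibrated so that the
  lifetime risk of diagnosis and the median age at onset among the diagnosed
  match the target setting.

Two settings are shipped: ``high`` (a common chronic disease with roughly
40% lifetime diagnosis risk and late onset, modelled on type 2 diabetes) and
``low`` (a rare disease with ~0.2% lifetime risk and early onset, modelled
on lupus erythematosus).

All rates are defined on the age interval [0, 110] years.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import integrate, optimize

AGE_MIN = 0.0
AGE_MAX = 110.0

#: Gompertz slope (per year) shared by both settings; a typical adult value.
DEFAULT_GOMPERTZ_SLOPE = 0.1

#: Quadrature relative tolerance for generic cumulative hazards.
QUAD_RTOL = 1e-10
#: Relative tolerance for incidence calibration residuals.
CALIBRATION_RTOL = 1e-6


class CalibrationError(RuntimeError):
    """Raised when rate calibration fails to reach its targets."""


def _check_age(a) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if np.any(a < AGE_MIN) or np.any(a > AGE_MAX):
        raise ValueError(f"age must lie in [{AGE_MIN}, {AGE_MAX}], got {a!r}")
    return a


def _expm1_ratio(x):
    """(exp(x) - 1)/x, stable near x = 0."""
    x = np.asarray(x, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(np.abs(x) < 1e-12, 1.0 + x / 2.0, np.expm1(x) / np.where(x == 0, 1.0, x))
    return out


@dataclass(frozen=True)
class GompertzHazard:
    """Hazard log-linear in age: rate(a) = exp(log_level + slope * a)."""

    log_level: float
    slope: float

    def rate(self, a):
        a = _check_age(a)
        return np.exp(self.log_level + self.slope * a)

    def cumulative(self, a0, a1):
        # closed form: exp(log_level) * (exp(slope*a1) - exp(slope*a0)) / slope
        a0 = np.asarray(a0, dtype=float)
        a1 = np.asarray(a1, dtype=float)
        da = a1 - a0
        return np.exp(self.log_level + self.slope * a0) * da * _expm1_ratio(self.slope * da)

    def inverse_cumulative(self, a0, target):
        """Age a with cumulative(a0, a) == target; +inf where unreachable by AGE_MAX."""
        a0 = np.asarray(a0, dtype=float)
        target = np.asarray(target, dtype=float)
        if self.slope == 0.0:
            a = a0 + target * np.exp(-self.log_level)
        else:
            arg = np.exp(self.slope * a0) + target * self.slope * np.exp(-self.log_level)
            a = np.log(arg) / self.slope
        return np.where(a <= AGE_MAX, a, np.inf)


@dataclass(frozen=True)
class LogLinearRatio:
    """Mortality rate ratio log-linear in age: MRR(a) = exp(intercept - decay * a)."""

    intercept: float
    decay: float

    def value(self, a):
        a = _check_age(a)
        return np.exp(self.intercept - self.decay * a)

    @classmethod
    def through(cls, a1: float, r1: float, a2: float, r2: float) -> "LogLinearRatio":
        """Log-linear ratio passing through (a1, r1) and (a2, r2)."""
        decay = (math.log(r1) - math.log(r2)) / (a2 - a1)
        intercept = math.log(r1) + decay * a1
        return cls(intercept=intercept, decay=decay)


@dataclass(frozen=True)
class IncidenceCurve:
    """Incidence zero below ``onset_age``, log-linear above it.

    rate(a) = exp(log_level + slope * (a - onset_age)) for a >= onset_age.
    """

    onset_age: float
    log_level: float
    slope: float

    def rate(self, a):
        a = _check_age(a)
        above = a >= self.onset_age
        r = np.exp(self.log_level + self.slope * (np.asarray(a, float) - self.onset_age))
        return np.where(above, r, 0.0)

    def cumulative(self, a0, a1):
        a0 = np.maximum(np.asarray(a0, dtype=float), self.onset_age)
        a1 = np.maximum(np.asarray(a1, dtype=float), self.onset_age)
        da = np.maximum(a1 - a0, 0.0)
        return np.exp(self.log_level + self.slope * (a0 - self.onset_age)) * da * _expm1_ratio(
            self.slope * da
        )


@dataclass(frozen=True)
class SumHazard:
    """Pointwise sum of hazards (the all-cause hazard m0 + i out of Healthy)."""

    parts: tuple

    def rate(self, a):
        return sum(p.rate(a) for p in self.parts)

    def cumulative(self, a0, a1):
        return sum(p.cumulative(a0, a1) for p in self.parts)


@dataclass(frozen=True)
class RateSet:
    """The three transition intensities of one IDM setting."""

    m0: GompertzHazard
    mrr: LogLinearRatio
    incidence: IncidenceCurve
    setting_label: str

    @property
    def m1(self) -> GompertzHazard:
        # m1 = m0 * MRR is again Gompertz: logs add.
        return GompertzHazard(
            log_level=self.m0.log_level + self.mrr.intercept,
            slope=self.m0.slope - self.mrr.decay,
        )

    @property
    def healthy_exit(self) -> SumHazard:
        """Combined hazard of leaving the Healthy state (death or diagnosis)."""
        return SumHazard(parts=(self.m0, self.incidence))


@dataclass(frozen=True)
class CalibrationTargets:
    """Published summary quantities a setting's rates are calibrated against."""

    lifetime_risk: float
    median_onset: float
    median_death_nondiseased: float

    def __post_init__(self):
        if not 0.0 <= self.lifetime_risk <= 1.0:
            raise ValueError("lifetime_risk must be a probability")
        if not 0.0 < self.median_onset < self.median_death_nondiseased <= AGE_MAX:
            raise ValueError("need 0 < median_onset < median_death_nondiseased <= 110")


HIGH_TARGETS = CalibrationTargets(
    lifetime_risk=0.40019, median_onset=60.75, median_death_nondiseased=74.00
)
LOW_TARGETS = CalibrationTargets(
    lifetime_risk=0.00196, median_onset=32.55, median_death_nondiseased=70.53
)

#: Age below which incidence is zero, per setting (late onset for the common
#: disease, early adult onset for the rare one).
ONSET_AGE = {"high": 30.0, "low": 18.0}


# ---------------------------------------------------------------------------
# generic operations


def hazard_at(rate, a):
    """Per-year intensity of any hazard/ratio object at age ``a`` (years)."""
    if isinstance(rate, LogLinearRatio):
        return rate.value(a)
    return rate.rate(a)


def cumulative_hazard(rate, a0, a1):
    """Integral of the hazard over [a0, a1]; closed form where available.

    Hazard objects without a ``cumulative`` method are integrated by adaptive
    quadrature at relative tolerance 1e-10.
    """
    a0 = _check_age(a0)
    a1 = _check_age(a1)
    if np.any(a1 < a0):
        raise ValueError("require a0 <= a1")
    if hasattr(rate, "cumulative"):
        return rate.cumulative(a0, a1)
    val, _ = integrate.quad(lambda x: float(hazard_at(rate, x)), float(a0), float(a1),
                            epsrel=QUAD_RTOL, epsabs=0.0, limit=200)
    return val


def mrr_value(ratio: LogLinearRatio, a):
    """True mortality rate ratio m1(a)/m0(a) at age ``a``."""
    return ratio.value(a)


# ---------------------------------------------------------------------------
# calibration


def calibrate_m0(target_median_death: float, slope_fixed: float = DEFAULT_GOMPERTZ_SLOPE) -> GompertzHazard:
    """Gompertz level such that the m0-only survival median equals the target.

    Solves exp(log_level) * (exp(slope*T) - 1)/slope = ln 2 in closed form.
    The selection effect of competing diagnosis is ignored here (the median
    printed for the non-diseased is treated as the unconditional m0 median);
    this is a documented approximation.
    """
    if not 40.0 < target_median_death < AGE_MAX:
        raise ValueError("target median death age must lie in (40, 110)")
    if slope_fixed <= 0:
        raise ValueError("slope must be positive")
    log_level = math.log(math.log(2.0) * slope_fixed / math.expm1(slope_fixed * target_median_death))
    return GompertzHazard(log_level=log_level, slope=slope_fixed)


def _diagnosis_density(incidence: IncidenceCurve, m0: GompertzHazard, a):
    """Sub-density of age at diagnosis: i(a) * exp(-Λ_i(0,a) - Λ_m0(0,a))."""
    a = np.asarray(a, dtype=float)
    lam = incidence.cumulative(0.0, a) + m0.cumulative(0.0, a)
    return incidence.rate(a) * np.exp(-lam)


def lifetime_risk(rates: RateSet) -> float:
    """Competing-risk probability of ever being diagnosed.

    ∫_0^110 i(a) exp(-Λ_i(0,a) - Λ_m0(0,a)) da.
    """
    return _cumulative_diagnosis_prob(rates.incidence, rates.m0, AGE_MAX)


def _cumulative_diagnosis_prob(incidence: IncidenceCurve, m0: GompertzHazard, upto: float) -> float:
    lo = incidence.onset_age
    if upto <= lo:
        return 0.0
    val, _ = integrate.quad(
        lambda a: float(_diagnosis_density(incidence, m0, a)), lo, upto,
        epsrel=1e-11, epsabs=1e-14, limit=200,
    )
    return val


def calibrate_incidence(
    targets: CalibrationTargets,
    m0: GompertzHazard,
    onset_age: float,
) -> IncidenceCurve:
    """Solve the two incidence parameters against lifetime risk and median onset.

    A two-dimensional root-find matches (a) the competing-risk lifetime
    probability of diagnosis and (b) the median of the onset-age distribution
    among the diagnosed.  Raises :class:`CalibrationError` with the residuals
    if the solver does not reach relative tolerance 1e-6.
    """
    risk = targets.lifetime_risk
    med = targets.median_onset
    if not 0.0 < risk < 1.0:
        raise ValueError("lifetime risk target must be in (0, 1)")
    if not onset_age < med < AGE_MAX:
        raise ValueError("median onset must lie in (onset_age, 110)")

    def residuals(x):
        curve = IncidenceCurve(onset_age=onset_age, log_level=x[0], slope=x[1])
        total = _cumulative_diagnosis_prob(curve, m0, AGE_MAX)
        half = _cumulative_diagnosis_prob(curve, m0, med)
        return [total / risk - 1.0, half / risk - 0.5]

    # ignore survival for the starting guess: flat rate spreading the target
    # risk over the at-risk ages
    x0 = [math.log(risk / (AGE_MAX - onset_age)), 0.0]
    sol = optimize.root(residuals, x0, method="hybr", tol=1e-12)
    res = residuals(sol.x)
    if max(abs(r) for r in res) > CALIBRATION_RTOL:
        raise CalibrationError(
            f"incidence calibration did not converge: residuals={res}, targets={targets}"
        )
    return IncidenceCurve(onset_age=onset_age, log_level=float(sol.x[0]), slope=float(sol.x[1]))


def calibrate_rates(
    targets: CalibrationTargets,
    onset_age: float,
    slope_fixed: float = DEFAULT_GOMPERTZ_SLOPE,
) -> tuple[GompertzHazard, IncidenceCurve]:
    """Jointly calibrate m0 and the incidence curve against all three targets.

    The closed-form :func:`calibrate_m0` treats the printed median death age
    of the non-diseased as the unconditional median of the m0-only process,
    but competing diagnosis selects earlier deaths into the non-diseased
    group (markedly so when lifetime risk is large), so that approximation
    biases the death-age distribution.  Here the three free parameters
    (m0 level, incidence level and slope) are solved simultaneously so that

    * the competing-risk lifetime probability of diagnosis,
    * the median onset age among the diagnosed, and
    * the median death age among those dying non-diseased

    all match the targets exactly.  The closed-form single-target solutions
    provide the starting point.
    """
    risk = targets.lifetime_risk
    med_on = targets.median_onset
    med_d = targets.median_death_nondiseased

    def resid(x):
        m0 = GompertzHazard(log_level=x[0], slope=slope_fixed)
        inc = IncidenceCurve(onset_age=onset_age, log_level=x[1], slope=x[2])

        def surv(a):
            return math.exp(-(float(m0.cumulative(0.0, a)) + float(inc.cumulative(0.0, a))))

        total, _ = integrate.quad(lambda a: float(inc.rate(a)) * surv(a),
                                  onset_age, AGE_MAX, epsrel=1e-11, limit=200)
        half, _ = integrate.quad(lambda a: float(inc.rate(a)) * surv(a),
                                 onset_age, med_on, epsrel=1e-11, limit=200)
        nd_half, _ = integrate.quad(lambda a: float(m0.rate(a)) * surv(a),
                                    0.0, med_d, epsrel=1e-11, limit=200)
        return [total / risk - 1.0, half / risk - 0.5, nd_half / ((1.0 - risk) / 2.0) - 1.0]

    m0_start = calibrate_m0(med_d, slope_fixed)
    inc_start = calibrate_incidence(targets, m0_start, onset_age)
    x0 = [m0_start.log_level, inc_start.log_level, inc_start.slope]
    sol = optimize.root(resid, x0, method="hybr", tol=1e-12)
    res = resid(sol.x)
    if max(abs(r) for r in res) > CALIBRATION_RTOL:
        raise CalibrationError(f"joint calibration did not converge: residuals={res}")
    return (
        GompertzHazard(log_level=float(sol.x[0]), slope=slope_fixed),
        IncidenceCurve(onset_age=onset_age, log_level=float(sol.x[1]), slope=float(sol.x[2])),
    )


@lru_cache(maxsize=None)
def default_rates(setting: str) -> RateSet:
    """Fully calibrated RateSet for the ``high`` or ``low`` incidence setting.

    high: MRR(a) = exp(2 - 0.02 a) (3.32 / 2.23 / 1.49 at ages 40/60/80);
    low:  MRR log-linear through (40, 3.79) and (80, 1.51).
    m0 and the incidence curve are the shipped results of
    :func:`calibrate_rates` for the setting's targets.
    """
    if setting == "high":
        targets = HIGH_TARGETS
        mrr = LogLinearRatio(intercept=2.0, decay=0.02)
    elif setting == "low":
        targets = LOW_TARGETS
        mrr = LogLinearRatio.through(40.0, 3.79, 80.0, 1.51)
    else:
        raise ValueError(f"unknown setting {setting!r}: expected 'high' or 'low'")
    m0, incidence = calibrate_rates(targets, ONSET_AGE[setting])
    return RateSet(m0=m0, mrr=mrr, incidence=incidence, setting_label=setting)


# ---------------------------------------------------------------------------
# serialization (flat keys, round-trips exactly)


def rates_to_dict(rates: RateSet) -> dict:
    return {
        "setting": rates.setting_label,
        "m0.log_level": rates.m0.log_level,
        "m0.slope": rates.m0.slope,
        "mrr.intercept": rates.mrr.intercept,
        "mrr.decay": rates.mrr.decay,
        "incidence.onset_age": rates.incidence.onset_age,
        "incidence.log_level": rates.incidence.log_level,
        "incidence.slope": rates.incidence.slope,
    }


def rates_from_dict(d: dict) -> RateSet:
    return RateSet(
        m0=GompertzHazard(log_level=float(d["m0.log_level"]), slope=float(d["m0.slope"])),
        mrr=LogLinearRatio(intercept=float(d["mrr.intercept"]), decay=float(d["mrr.decay"])),
        incidence=IncidenceCurve(
            onset_age=float(d["incidence.onset_age"]),
            log_level=float(d["incidence.log_level"]),
            slope=float(d["incidence.slope"]),
        ),
        setting_label=str(d["setting"]),
    )
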
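"""Person-time tables and Poisson log-linear estimation of mortality rates.

Life courses are split into one-year age bands on the estimation window
[40, 80): each life contributes non-diseased person-time from age 40 up to
diagnosis (or death, or 80, whichever is first) and diseased person-time
from diagnosis to death (both clipped to the window).  The death is counted
as an event in the band containing the death age, attributed to the state
occupied at death, and only if it falls inside the window; deaths at or
beyond 80 are censored at 80.  Under MicDaD the split uses the *observed*
diagnosis, so a masked individual's diseased time and death are wrongly
booked as non-diseased — masking reallocates person-time between groups but
never creates or destroys it.

Rates per group are modelled as log-linear in age, ``λ(a) = exp(β0 + β1 a)``
with person-years as exposure, and fitted by Newton–Raphson on the Poisson
likelihood with the band midpoint as the age covariate.  The mortality rate
ratio is the ratio of the two fitted rate curves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

WINDOW = (40.0, 80.0)
BAND_WIDTH = 1.0

GROUP_DISEASED = "diseased"
GROUP_NONDISEASED = "nondiseased"


class NoEventsError(ValueError):
    """Raised when a person-time table has no deaths to fit."""


@dataclass(frozen=True)
class PoissonFit:
    """Fitted log-linear Poisson rate: λ(a) = exp(intercept + slope * a)."""

    intercept: float
    slope: float
    converged: bool
    loglik: float

    def rate(self, a):
        return np.exp(self.intercept + self.slope * np.asarray(a, dtype=float))


@dataclass(frozen=True)
class MrrEstimate:
    age: float
    value: float


def split_person_time(
    lives: pd.DataFrame,
    use_observed: bool = False,
    window: tuple[float, float] = WINDOW,
    band_width: float = BAND_WIDTH,
) -> pd.DataFrame:
    """Tabulate deaths and person-years per (group, 1-year age band).

    ``use_observed`` selects the observed (post-masking) diagnosis instead of
    the true one.  Returns a DataFrame with columns group, band_start,
    events, person_years covering every band in the window for both groups.
    """
    lo, hi = window
    n_bands = (hi - lo) / band_width
    if not (hi > lo and abs(n_bands - round(n_bands)) < 1e-9):
        raise ValueError("band_width must evenly divide the window")
    n_bands = int(round(n_bands))
    edges = lo + band_width * np.arange(n_bands)

    col = "observed_diagnosis" if use_observed else "age_diagnosis"
    if col not in lives.columns:
        raise ValueError(f"population table lacks column {col!r}")
    diag = lives[col].to_numpy(dtype=float)
    death = lives["age_death"].to_numpy(dtype=float)
    has_diag = ~np.isnan(diag)

    # non-diseased episode: [lo, min(diag, death, hi))
    nd_lo = np.full_like(death, lo)
    nd_hi = np.minimum(np.where(has_diag, diag, np.inf), np.minimum(death, hi))
    # diseased episode: [max(diag, lo), min(death, hi)) when diagnosed before hi
    d_lo = np.where(has_diag, np.maximum(diag, lo), np.nan)
    d_hi = np.where(has_diag & (diag < hi), np.minimum(death, hi), np.nan)

    def band_py(a, b):
        a = a[:, None]
        b = b[:, None]
        overlap = np.minimum(b, edges + band_width) - np.maximum(a, edges)
        return np.clip(np.nan_to_num(overlap, nan=0.0), 0.0, band_width).sum(axis=0)

    py_nd = band_py(nd_lo, nd_hi)
    py_d = band_py(d_lo, d_hi)

    in_window = (death >= lo) & (death < hi)
    death_band = np.floor((death[in_window] - lo) / band_width).astype(int)
    died_diseased = has_diag[in_window]  # diagnosis always precedes death
    ev_nd = np.bincount(death_band[~died_diseased], minlength=n_bands)
    ev_d = np.bincount(death_band[died_diseased], minlength=n_bands)

    cells = pd.DataFrame({
        "group": [GROUP_NONDISEASED] * n_bands + [GROUP_DISEASED] * n_bands,
        "band_start": np.concatenate([edges, edges]),
        "events": np.concatenate([ev_nd, ev_d]).astype(int),
        "person_years": np.concatenate([py_nd, py_d]),
    })
    # a death at an exact band edge can land in a band where the individual
    # accrued no exposure (probability zero under continuous ages); such
    # cells are kept here and excluded by the fit's person-time filter
    return cells


def fit_poisson_loglinear(
    cells: pd.DataFrame,
    fixed_slope: Optional[float] = None,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> PoissonFit:
    """Maximum-likelihood log-linear Poisson rate fit for one group's cells.

    Newton–Raphson from an intercept-only start; converged when the largest
    parameter change drops below ``tol``.  With ``fixed_slope`` the slope is
    held and only the intercept estimated (a single band then suffices).
    """
    use = cells[cells["person_years"] > 0]
    d = use["events"].to_numpy(dtype=float)
    py = use["person_years"].to_numpy(dtype=float)
    a = use["band_start"].to_numpy(dtype=float) + BAND_WIDTH / 2.0

    if d.sum() == 0:
        raise NoEventsError("no deaths in person-time table")
    if fixed_slope is None and len(use) < 2:
        raise ValueError("need at least two bands with person-time to fit a slope")

    beta = np.array([np.log(d.sum() / py.sum()), 0.0 if fixed_slope is None else fixed_slope])
    converged = False
    for _ in range(max_iter):
        mu = np.exp(beta[0] + beta[1] * a) * py
        score = np.array([np.sum(d - mu), np.sum(a * (d - mu))])
        hess = np.array([[np.sum(mu), np.sum(a * mu)],
                         [np.sum(a * mu), np.sum(a * a * mu)]])
        if fixed_slope is not None:
            step = np.array([score[0] / hess[0, 0], 0.0])
        else:
            step = np.linalg.solve(hess, score)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break

    mu = np.exp(beta[0] + beta[1] * a) * py
    eta = beta[0] + beta[1] * a
    loglik = float(np.sum(d * (eta + np.log(py)) - mu))
    return PoissonFit(intercept=float(beta[0]), slope=float(beta[1]),
                      converged=converged, loglik=loglik)


def mrr_curve(
    fit_diseased: PoissonFit, fit_nondiseased: PoissonFit, ages
) -> list[MrrEstimate]:
    """Mortality rate ratio m1(a)/m0(a) of two fitted rate curves."""
    if not (fit_diseased.converged and fit_nondiseased.converged):
        raise ValueError("both Poisson fits must have converged")
    d0 = fit_diseased.intercept - fit_nondiseased.intercept
    d1 = fit_diseased.slope - fit_nondiseased.slope
    return [MrrEstimate(age=float(a), value=float(np.exp(d0 + d1 * a))) for a in np.atleast_1d(ages)]
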
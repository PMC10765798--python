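"""Person-time splitting and Poisson log-linear rate estimation."""

import math

import numpy as np
import pandas as pd
import pytest

from micdad import (
    NoEventsError,
    fit_poisson_loglinear,
    mrr_curve,
    split_person_time,
)
from micdad.poisson import GROUP_DISEASED, GROUP_NONDISEASED, PoissonFit


def _pop(rows):
    return pd.DataFrame(rows, columns=["id", "age_diagnosis", "age_death",
                                       "observed_diagnosis"])


def _totals(cells, group):
    g = cells[cells.group == group]
    return g.person_years.sum(), g.events.sum()


# ---------------------------------------------------------------------------
# person-time splitting


def test_split_disease_free_life():
    cells = split_person_time(_pop([(0, np.nan, 75.0, np.nan)]))
    py_nd, ev_nd = _totals(cells, GROUP_NONDISEASED)
    py_d, ev_d = _totals(cells, GROUP_DISEASED)
    assert py_nd == pytest.approx(35.0)
    assert (ev_nd, py_d, ev_d) == (1, 0.0, 0)
    band = cells[(cells.group == GROUP_NONDISEASED) & (cells.events > 0)]
    assert list(band.band_start) == [75.0]


def test_split_diagnosed_life_true_status():
    cells = split_person_time(_pop([(0, 60.0, 70.0, np.nan)]), use_observed=False)
    assert _totals(cells, GROUP_NONDISEASED) == (pytest.approx(20.0), 0)
    py_d, ev_d = _totals(cells, GROUP_DISEASED)
    assert py_d == pytest.approx(10.0) and ev_d == 1


def test_split_masked_life_books_everything_nondiseased():
    # surveyed at 50, diagnosed at 60: the diagnosis is unseen, so all time
    # and the death are wrongly non-diseased
    cells = split_person_time(_pop([(0, 60.0, 70.0, np.nan)]), use_observed=True)
    py_nd, ev_nd = _totals(cells, GROUP_NONDISEASED)
    assert py_nd == pytest.approx(30.0) and ev_nd == 1
    assert _totals(cells, GROUP_DISEASED) == (0.0, 0)


def test_split_censors_deaths_beyond_window():
    cells = split_person_time(_pop([(0, 60.0, 95.0, 60.0)]))
    assert _totals(cells, GROUP_NONDISEASED) == (pytest.approx(20.0), 0)
    assert _totals(cells, GROUP_DISEASED) == (pytest.approx(20.0), 0)  # no event: death >= 80


def test_split_rejects_uneven_window():
    with pytest.raises(ValueError):
        split_person_time(_pop([(0, np.nan, 75.0, np.nan)]), window=(40.0, 80.0), band_width=3.0)


def test_person_time_conserved_under_masking(high_surveyed):
    surveyed, _ = high_surveyed
    sub = surveyed.iloc[:20_000]
    truth = split_person_time(sub, use_observed=False)
    masked = split_person_time(sub, use_observed=True)
    # masking reallocates time and events between groups, never totals
    assert truth.person_years.sum() == pytest.approx(masked.person_years.sum(), rel=1e-12)
    assert truth.events.sum() == masked.events.sum()


def test_masking_monotonicity_bandwise(high_surveyed):
    surveyed, _ = high_surveyed
    sub = surveyed.iloc[:20_000]
    truth = split_person_time(sub, use_observed=False)
    masked = split_person_time(sub, use_observed=True)
    t_nd = truth[truth.group == GROUP_NONDISEASED].set_index("band_start")
    m_nd = masked[masked.group == GROUP_NONDISEASED].set_index("band_start")
    assert (m_nd.person_years >= t_nd.person_years - 1e-9).all()
    assert (m_nd.events >= t_nd.events).all()


# ---------------------------------------------------------------------------
# Poisson fit


def test_two_band_saturated_closed_form():
    cells = pd.DataFrame({
        "group": GROUP_NONDISEASED,
        "band_start": [49.5, 69.5],  # midpoints 50 and 70
        "events": [2, 8],
        "person_years": [100.0, 100.0],
    })
    fit = fit_poisson_loglinear(cells)
    slope = math.log(4) / 20
    assert fit.converged
    assert fit.slope == pytest.approx(slope, abs=1e-9)
    assert fit.intercept == pytest.approx(math.log(0.02) - 50 * slope, abs=1e-9)


def test_single_band_fixed_slope_rate():
    cells = pd.DataFrame({"group": GROUP_NONDISEASED, "band_start": [59.5],
                          "events": [5], "person_years": [100.0]})
    fit = fit_poisson_loglinear(cells, fixed_slope=0.0)
    assert math.exp(fit.intercept) == pytest.approx(0.05, rel=1e-10)


def test_fit_errors():
    no_events = pd.DataFrame({"group": GROUP_NONDISEASED, "band_start": [50.0, 51.0],
                              "events": [0, 0], "person_years": [10.0, 10.0]})
    with pytest.raises(NoEventsError):
        fit_poisson_loglinear(no_events)
    one_band = pd.DataFrame({"group": GROUP_NONDISEASED, "band_start": [50.0],
                             "events": [2], "person_years": [10.0]})
    with pytest.raises(ValueError):
        fit_poisson_loglinear(one_band)


def _loglik(beta, cells):
    d = cells.events.to_numpy(float)
    py = cells.person_years.to_numpy(float)
    a = cells.band_start.to_numpy(float) + 0.5
    eta = beta[0] + beta[1] * a
    return float(np.sum(d * (eta + np.log(py)) - np.exp(eta) * py))


def _grid_mle(cells, ref_age=60.0, levels=7, points=41):
    """Brute-force zooming likelihood grid search, independent of Newton.

    Searches the better-conditioned (rate at ref_age, slope) plane and maps
    back to the age-0 intercept.
    """
    d = cells.events.to_numpy(float)
    py = cells.person_years.to_numpy(float)
    c, b = math.log(d.sum() / py.sum()), 0.0
    wc, wb = 1.0, 0.15
    for _ in range(levels):
        gc = np.linspace(c - wc, c + wc, points)
        gb = np.linspace(b - wb, b + wb, points)
        ll = np.array([[_loglik((x0 - ref_age * x1, x1), cells) for x1 in gb] for x0 in gc])
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        c, b = gc[i], gb[j]
        wc /= points / 5
        wb /= points / 5
    return c - ref_age * b, b


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_newton_matches_brute_force_grid(seed):
    rng = np.random.default_rng(seed)
    bands = 40.0 + np.arange(8) * 5.0
    py = rng.uniform(50, 500, size=len(bands))
    true_rate = np.exp(-9.0 + 0.09 * (bands + 0.5))
    events = rng.poisson(true_rate * py)
    cells = pd.DataFrame({"group": GROUP_NONDISEASED, "band_start": bands,
                          "events": events, "person_years": py})
    assert events.sum() > 0  # hazard scale chosen to guarantee events
    fit = fit_poisson_loglinear(cells)
    b0, b1 = _grid_mle(cells)
    assert fit.intercept == pytest.approx(b0, abs=1e-4)
    assert fit.slope == pytest.approx(b1, abs=1e-4)


def test_newton_matches_statsmodels_glm(rng):
    sm = pytest.importorskip("statsmodels.api")
    bands = 40.0 + np.arange(40)
    py = rng.uniform(100, 1000, size=40)
    events = rng.poisson(np.exp(-10.0 + 0.1 * (bands + 0.5)) * py)
    cells = pd.DataFrame({"group": GROUP_NONDISEASED, "band_start": bands,
                          "events": events, "person_years": py})
    fit = fit_poisson_loglinear(cells)
    X = sm.add_constant(bands + 0.5)
    glm = sm.GLM(events, X, family=sm.families.Poisson(), exposure=py).fit()
    assert fit.intercept == pytest.approx(glm.params[0], abs=1e-7)
    assert fit.slope == pytest.approx(glm.params[1], abs=1e-9)
    assert fit.loglik == pytest.approx(
        float(np.sum(events * (X @ glm.params + np.log(py))
                     - np.exp(X @ glm.params) * py)), rel=1e-9)


def _fit_se(cells):
    """Asymptotic standard errors from the observed information."""
    fit = fit_poisson_loglinear(cells)
    use = cells[cells.person_years > 0]
    a = use.band_start.to_numpy(float) + 0.5
    mu = np.exp(fit.intercept + fit.slope * a) * use.person_years.to_numpy(float)
    hess = np.array([[mu.sum(), (a * mu).sum()], [(a * mu).sum(), (a * a * mu).sum()]])
    return fit, np.sqrt(np.diag(np.linalg.inv(hess)))


def test_gompertz_slope_recovered_from_simulated_cohort(high_surveyed):
    # the non-diseased rate is Gompertz with slope 0.1 by construction
    surveyed, _ = high_surveyed
    cells = split_person_time(surveyed, use_observed=False)
    fit, se = _fit_se(cells[cells.group == GROUP_NONDISEASED])
    assert abs(fit.slope - 0.1) < 3 * se[1]


def test_input_mrr_recovered_without_masking(high_rates, high_surveyed):
    surveyed, _ = high_surveyed
    cells = split_person_time(surveyed, use_observed=False)
    fit_d, se_d = _fit_se(cells[cells.group == GROUP_DISEASED])
    fit_n, se_n = _fit_se(cells[cells.group == GROUP_NONDISEASED])
    for age in (40.0, 60.0, 80.0):
        est = mrr_curve(fit_d, fit_n, [age])[0].value
        true = math.exp(high_rates.mrr.intercept - high_rates.mrr.decay * age)
        se_log = math.sqrt(se_d[0] ** 2 + se_n[0] ** 2
                           + age ** 2 * (se_d[1] ** 2 + se_n[1] ** 2))
        assert abs(math.log(est) - math.log(true)) < 3 * se_log


# ---------------------------------------------------------------------------
# MRR curve


def test_mrr_curve_identical_fits_is_unity():
    fit = PoissonFit(intercept=-10.0, slope=0.1, converged=True, loglik=0.0)
    assert all(e.value == pytest.approx(1.0) for e in mrr_curve(fit, fit, [40, 60, 80]))


def test_mrr_curve_log_linear_difference():
    fit_n = PoissonFit(intercept=-10.0, slope=0.1, converged=True, loglik=0.0)
    fit_d = PoissonFit(intercept=-8.0, slope=0.08, converged=True, loglik=0.0)
    vals = {e.age: e.value for e in mrr_curve(fit_d, fit_n, [40.0, 60.0])}
    assert vals[60.0] == pytest.approx(math.exp(0.8), rel=1e-12)
    assert round(vals[40.0], 2) == 3.32


def test_mrr_curve_requires_convergence():
    ok = PoissonFit(intercept=-10.0, slope=0.1, converged=True, loglik=0.0)
    bad = PoissonFit(intercept=-8.0, slope=0.08, converged=False, loglik=0.0)
    with pytest.raises(ValueError):
        mrr_curve(bad, ok, [60.0])
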
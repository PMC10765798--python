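"""Discrete-event simulation of life courses through the illness-death model.

Each individual starts Healthy at birth (age 0).  The age of the first
transition is drawn from the combined hazard ``m0(a) + i(a)`` by inverting
the cumulative hazard at an exponential deviate; the event is a diagnosis
with probability ``i(a*) / (i(a*) + m0(a*))`` at the realized age, otherwise
a death.  Diagnosed individuals draw a second event age — death — from the
diseased mortality ``m1`` starting at the diagnosis age.  Anyone still
event-free at age 110 is assigned death at exactly 110, so Death is the
final state of every simulated life.

Populations are held as a pandas DataFrame with columns ``id``,
``age_diagnosis`` (NaN when disease-free at death) and ``age_death``;
:class:`LifeCourse` is the scalar record.  Populations round-trip through a
Lexis-style long format (one row per state episode) for storage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .hazards import AGE_MAX, RateSet, cumulative_hazard

_BISECT_ITER = 60  # (110 - 0) / 2**60 ≈ 1e-16 years


@dataclass(frozen=True)
class LifeCourse:
    """One simulated life: optional diagnosis age, mandatory death age."""

    id: int
    age_diagnosis: Optional[float]
    age_death: float

    def __post_init__(self):
        if not 0.0 < self.age_death <= AGE_MAX:
            raise ValueError("age_death must lie in (0, 110]")
        if self.age_diagnosis is not None and not 0.0 < self.age_diagnosis < self.age_death:
            raise ValueError("age_diagnosis must lie in (0, age_death)")


@dataclass(frozen=True)
class SimConfig:
    """Population size, age cap and seed of one simulation run."""

    n_individuals: int = 100_000
    age_cap: float = AGE_MAX
    seed: int = 0

    def __post_init__(self):
        if self.n_individuals < 0:
            raise ValueError("n_individuals must be nonnegative")
        if self.age_cap != AGE_MAX:
            raise ValueError("age_cap is fixed at 110")


@dataclass(frozen=True)
class TransitionTable:
    """Counts of the three possible transitions of the chronic-disease IDM."""

    healthy_to_disease: int
    healthy_to_death: int
    disease_to_death: int


def sample_event_age(hazard, start_age: float, u: float) -> float:
    """Event age with survival u from ``start_age`` under ``hazard``.

    Solves ``Λ(start_age, a*) = -ln u`` by monotone bisection; returns
    ``inf`` (cap-censored) when the total hazard up to age 110 is smaller
    than ``-ln u``.
    """
    if not 0.0 < u < 1.0:
        raise ValueError("u must lie in (0, 1)")
    if not 0.0 <= start_age < AGE_MAX:
        raise ValueError("start_age must lie in [0, 110)")
    return float(_invert_cumhaz(hazard, np.array([start_age]), np.array([-np.log(u)]))[0])


def _invert_cumhaz(hazard, start_ages: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Vectorized bisection for Λ(start, a) = target on [start, 110].

    Entries whose total hazard to 110 falls short of the target come back
    as +inf (cap-censored).
    """
    total = np.asarray(cumulative_hazard(hazard, start_ages, np.full_like(start_ages, AGE_MAX)))
    censored = total < targets
    lo = start_ages.astype(float).copy()
    hi = np.full_like(lo, AGE_MAX)
    for _ in range(_BISECT_ITER):
        mid = 0.5 * (lo + hi)
        below = np.asarray(cumulative_hazard(hazard, start_ages, mid)) < targets
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    out = 0.5 * (lo + hi)
    return np.where(censored, np.inf, out)


def simulate_life(rates: RateSet, rng: np.random.Generator, id: int = 0) -> LifeCourse:
    """Simulate a single life course (scalar convenience wrapper)."""
    df, _ = simulate_population(SimConfig(n_individuals=1, seed=0), rates, rng=rng)
    row = df.iloc[0]
    diag = None if np.isnan(row.age_diagnosis) else float(row.age_diagnosis)
    return LifeCourse(id=id, age_diagnosis=diag, age_death=float(row.age_death))


def simulate_population(
    config: SimConfig, rates: RateSet, rng: Optional[np.random.Generator] = None
) -> tuple[pd.DataFrame, TransitionTable]:
    """Simulate ``config.n_individuals`` independent lives.

    Deterministic for a fixed seed (one RNG stream per population).  Returns
    the population DataFrame (id, age_diagnosis, age_death) and its
    transition table.
    """
    n = config.n_individuals
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if n == 0:
        df = pd.DataFrame({"id": pd.Series([], dtype=int),
                           "age_diagnosis": pd.Series([], dtype=float),
                           "age_death": pd.Series([], dtype=float)})
        return df, TransitionTable(0, 0, 0)

    exit_hazard = rates.healthy_exit
    u1 = rng.random(n)
    type_draw = rng.random(n)
    u2 = rng.random(n)

    first_age = _invert_cumhaz(exit_hazard, np.zeros(n), -np.log(u1))
    capped = ~np.isfinite(first_age)
    eval_age = np.where(capped, AGE_MAX, first_age)

    i_rate = rates.incidence.rate(eval_age)
    m0_rate = rates.m0.rate(eval_age)
    p_disease = np.where(i_rate + m0_rate > 0, i_rate / (i_rate + m0_rate), 0.0)
    diseased = (~capped) & (type_draw < p_disease)

    age_diagnosis = np.full(n, np.nan)
    age_death = np.where(capped, AGE_MAX, first_age)

    if diseased.any():
        d_ages = first_age[diseased]
        age_diagnosis[diseased] = d_ages
        # m1 = m0 * MRR is Gompertz, so the inverse cumulative hazard is closed form
        second = rates.m1.inverse_cumulative(d_ages, -np.log(u2[diseased]))
        age_death[diseased] = np.where(np.isfinite(second), second, AGE_MAX)

    df = pd.DataFrame({
        "id": np.arange(n, dtype=int),
        "age_diagnosis": age_diagnosis,
        "age_death": age_death,
    })
    return df, transition_counts(df)


def transition_counts(population: pd.DataFrame) -> TransitionTable:
    """Tally the IDM transitions realized in a simulated population."""
    n = len(population)
    n_diag = int(population["age_diagnosis"].notna().sum())
    return TransitionTable(
        healthy_to_disease=n_diag,
        healthy_to_death=n - n_diag,
        disease_to_death=n_diag,
    )


# ---------------------------------------------------------------------------
# Lexis-style storage: one row per state episode


def to_lexis(population: pd.DataFrame) -> pd.DataFrame:
    """Long-format episodes: id, age_in, age_out, state_in (H/D), state_out (H/D/X)."""
    diag = population["age_diagnosis"].to_numpy()
    death = population["age_death"].to_numpy()
    ids = population["id"].to_numpy()
    has_d = ~np.isnan(diag)

    healthy = pd.DataFrame({
        "id": ids,
        "age_in": 0.0,
        "age_out": np.where(has_d, diag, death),
        "state_in": "H",
        "state_out": np.where(has_d, "D", "X"),
    })
    disease = pd.DataFrame({
        "id": ids[has_d],
        "age_in": diag[has_d],
        "age_out": death[has_d],
        "state_in": "D",
        "state_out": "X",
    })
    out = pd.concat([healthy, disease], ignore_index=True)
    return out.sort_values(["id", "age_in"], kind="stable").reset_index(drop=True)


def from_lexis(lexis: pd.DataFrame) -> pd.DataFrame:
    """Reconstruct the (id, age_diagnosis, age_death) population table."""
    death = lexis[lexis["state_out"] == "X"][["id", "age_out"]].rename(
        columns={"age_out": "age_death"})
    diag = lexis[(lexis["state_in"] == "H") & (lexis["state_out"] == "D")][
        ["id", "age_out"]].rename(columns={"age_out": "age_diagnosis"})
    df = death.merge(diag, on="id", how="left")
    return df[["id", "age_diagnosis", "age_death"]].sort_values("id").reset_index(drop=True)
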
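"""One-time survey participation and misclassification of disease status at death.

Each individual is surveyed once, at an age drawn uniformly on [18, 110].
A diagnosis that happens strictly after the survey is never recorded, so the
individual is misclassified as disease-free at death (MicDaD).  Masking
touches only the observed diagnosis: death ages and population size are
never altered, and a diagnosis is never invented.

The boundary tie ``age_survey == age_diagnosis`` counts as observed (the
rule hides strictly later diagnoses); this has probability zero under
continuous ages but is fixed for reproducibility.  Surveys that fall after
an individual's death keep the literal rule — masked iff survey < diagnosis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .idm import LifeCourse

SURVEY_LO = 18.0
SURVEY_HI = 110.0


@dataclass(frozen=True)
class SurveyedLife:
    """A life course with its survey age and the observed (possibly masked) diagnosis."""

    life: LifeCourse
    age_survey: float
    observed_diagnosis: Optional[float]


def assign_survey_ages(
    population: pd.DataFrame,
    rng: np.random.Generator,
    lo: float = SURVEY_LO,
    hi: float = SURVEY_HI,
) -> np.ndarray:
    """Independent Uniform(lo, hi) survey ages, one per individual."""
    if lo >= hi:
        raise ValueError("survey age bounds require lo < hi")
    return rng.uniform(lo, hi, size=len(population))


def apply_micdad(life: LifeCourse, age_survey: float) -> SurveyedLife:
    """Mask the diagnosis if it happened strictly after survey participation."""
    if not SURVEY_LO <= age_survey <= SURVEY_HI:
        raise ValueError("age_survey must lie in [18, 110]")
    observed = life.age_diagnosis
    if observed is not None and age_survey < observed:
        observed = None
    return SurveyedLife(life=life, age_survey=age_survey, observed_diagnosis=observed)


def apply_micdad_population(population: pd.DataFrame, survey_ages: np.ndarray) -> pd.DataFrame:
    """Vectorized masking: adds ``age_survey`` and ``observed_diagnosis`` columns."""
    if len(survey_ages) != len(population):
        raise ValueError("one survey age per individual required")
    out = population.copy()
    diag = out["age_diagnosis"].to_numpy()
    masked = np.asarray(survey_ages) < diag  # NaN diag compares False: stays unobserved
    out["age_survey"] = np.asarray(survey_ages, dtype=float)
    out["observed_diagnosis"] = np.where(masked, np.nan, diag)
    return out


def misclassification_fraction(surveyed: pd.DataFrame) -> float:
    """Among truly diagnosed individuals, the fraction whose diagnosis was masked."""
    if len(surveyed) == 0:
        raise ValueError("empty population")
    diagnosed = surveyed["age_diagnosis"].notna()
    n_diag = int(diagnosed.sum())
    if n_diag == 0:
        raise ValueError("no diagnosed individuals: masked fraction undefined")
    n_masked = int((diagnosed & surveyed["observed_diagnosis"].isna()).sum())
    return n_masked / n_diag
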
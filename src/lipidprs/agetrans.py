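"""Sine age transform and the linear-vs-sine model-fit comparison.

Lipid levels follow a roughly sigmoidal trend over the lifespan.  Within a
linear mixed-model framework that trend can be captured by replacing the
linear age term with

    f(age) = sin( (pi/2) * (2*age - a_max - a_min) / (a_max - a_min) )

which rises from -1 at the study minimum age to +1 at the study maximum
age, steepest in the middle of the observed span.  ``compare_age_models``
fits the covariate-only random-intercept model both ways (age linear vs
f(age)) by maximum likelihood and reports the two AIC values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .datamodel import LongCohort
from .lmm import LMMSpec, fit_lmm

_log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AgeTransform:
    """Sine transform anchored at the training-data age extremes."""

    a_min: float
    a_max: float

    def __post_init__(self) -> None:
        if not self.a_max > self.a_min:
            raise ValueError(
                f"a_max ({self.a_max}) must exceed a_min ({self.a_min})"
            )

    def __call__(self, age) -> np.ndarray | float:
        return f_age(age, self)

    @classmethod
    def from_ages(cls, ages) -> "AgeTransform":
        ages = np.asarray(ages, dtype=float)
        return cls(float(ages.min()), float(ages.max()))


def f_age(age, t: AgeTransform):
    """Evaluate the sine age transform; maps [a_min, a_max] onto [-1, 1].

    Ages outside the anchored span (e.g. a test subject older than every
    training subject) are clamped to the boundary with a warning.
    """
    age = np.asarray(age, dtype=float)
    scalar = age.ndim == 0
    if np.any(age < t.a_min) or np.any(age > t.a_max):
        warnings.warn(
            f"age outside [{t.a_min}, {t.a_max}] clamped to boundary",
            stacklevel=2,
        )
        age = np.clip(age, t.a_min, t.a_max)
    z = (2.0 * age - t.a_max - t.a_min) / (t.a_max - t.a_min)
    out = np.sin(0.5 * np.pi * z)
    return float(out) if scalar else out


def compare_age_models(cohort: LongCohort, trait: str) -> tuple[float, float]:
    """AIC of the non-genetic mixed model with linear vs sine age.

    Both models share the random structure (subject intercept) and fixed
    covariates (intercept, age term, sex, BMI); they differ only in the age
    term, so they have equal dimension and their maximum-likelihood AICs
    are directly comparable.  Returns ``(aic_linear, aic_sine)``.
    """
    df = cohort.phenotypes.df
    y = cohort.phenotypes.trait_values(trait).to_numpy(dtype=float)
    keep = ~np.isnan(y)
    y = y[keep]
    age = df["age"].to_numpy(dtype=float)[keep]
    sex = df["sex"].to_numpy(dtype=float)[keep]
    bmi = df["bmi"].to_numpy(dtype=float)[keep]
    groups = df["subject_id"].to_numpy()[keep]
    t = AgeTransform.from_ages(age)

    ones = np.ones_like(age)
    X_lin = np.column_stack([ones, age, sex, bmi])
    X_sin = np.column_stack([ones, f_age(age, t), sex, bmi])

    fit_lin = fit_lmm(LMMSpec(y, X_lin, groups), method="ML")
    fit_sin = fit_lmm(LMMSpec(y, X_sin, groups), method="ML")
    _log.info(
        "%s age-model comparison: AIC linear=%.2f sine=%.2f",
        trait, fit_lin.aic, fit_sin.aic,
    )
    return fit_lin.aic, fit_sin.aic
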
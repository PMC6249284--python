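"""Residualized reading-comprehension phenotype and group classification.

Reading comprehension is regressed on age, performance IQ, two word-decoding
measures and three word-recognition measures; the standardized residual z
(residual / in-sample residual SD) defines the comprehension groups:

* UPC (unexpected poor comprehension):  z <= -1
* EAC (expected average comprehension): |z| <= 0.5
* UGC (unexpected good comprehension):  z >= +1

Subjects between 0.5 and 1 SD from the regression line are UNCLASSIFIED
under the standard banding; the "contiguous" banding used in sensitivity
analysis absorbs them into EAC (|z| < 1), and a "split" variant assigns
them outward at |z| >= 0.75.  Boundary values are inclusive toward the
extreme groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

UPC, EAC, UGC, UNCLASSIFIED = "UPC", "EAC", "UGC", "UNCLASSIFIED"

#: Predictors of the main-cohort residualization (standard scores).
DEFAULT_PREDICTORS = (
    "age_months",
    "piq",
    "wj_word_attack",
    "towre_pde",
    "wj_lwid",
    "towre_swe",
    "sri_word_recognition",
)

#: Imaging-subset variant: raw scores, word recognition collapsed to two tests.
IMAGING_PREDICTORS = (
    "age_months",
    "piq",
    "wj_word_attack",
    "towre_pde",
    "wj_lwid",
    "towre_swe",
)


class DegenerateFitError(ValueError):
    """Residual SD is (numerically) zero: the outcome is an exact linear
    function of the predictors, so residual banding is undefined."""


class SingularDesignError(ValueError):
    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"rank-deficient design; collinear columns: {self.columns}")


@dataclass
class ResidualModel:
    coefficients: dict
    intercept: float
    residual_sd: float
    n_fit: int
    predictors: tuple

    def predict(self, cohort: pd.DataFrame) -> np.ndarray:
        X = cohort[list(self.predictors)].to_numpy(float)
        beta = np.array([self.coefficients[p] for p in self.predictors])
        return self.intercept + X @ beta

    def residualize(self, cohort: pd.DataFrame, outcome: str = "sri_comprehension"):
        """Raw and standardized residuals for (possibly new) subjects."""
        resid = cohort[outcome].to_numpy(float) - self.predict(cohort)
        return resid, resid / self.residual_sd

    def to_dict(self) -> dict:
        return {
            "coefficients": dict(self.coefficients),
            "intercept": self.intercept,
            "residual_sd": self.residual_sd,
            "n_fit": self.n_fit,
            "predictors": list(self.predictors),
        }


def fit_residual_model(
    cohort: pd.DataFrame,
    outcome: str = "sri_comprehension",
    predictors: Sequence[str] = DEFAULT_PREDICTORS,
) -> ResidualModel:
    """OLS of comprehension on the decoding/recognition predictor set.

    Complete cases only; residual_sd is the SD of in-sample residuals
    (ddof=0, matching the "SD around the regression line" banding).
    """
    predictors = tuple(predictors)
    cols = [outcome, *predictors]
    data = cohort[cols].dropna()
    n = len(data)
    if n < len(predictors) + 2:
        raise ValueError(
            f"need >= {len(predictors) + 2} complete cases, got {n}"
        )
    X = np.column_stack([np.ones(n), data[list(predictors)].to_numpy(float)])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = _collinear_columns(X[:, 1:], predictors)
        raise SingularDesignError(bad)
    y = data[outcome].to_numpy(float)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sd = float(np.std(resid))
    if sd <= 1e-10 * max(1.0, float(np.std(y))):
        raise DegenerateFitError("all residuals are zero; banding undefined")
    return ResidualModel(
        coefficients=dict(zip(predictors, beta[1:])),
        intercept=float(beta[0]),
        residual_sd=sd,
        n_fit=n,
        predictors=predictors,
    )


def _collinear_columns(X: np.ndarray, names: Sequence[str]) -> list:
    bad = []
    for j in range(X.shape[1]):
        others = np.delete(X, j, axis=1)
        A = np.column_stack([np.ones(len(X)), others])
        resid = X[:, j] - A @ np.linalg.lstsq(A, X[:, j], rcond=None)[0]
        if np.linalg.norm(resid) < 1e-8 * max(1.0, np.linalg.norm(X[:, j])):
            bad.append(names[j])
    return bad or list(names)


def classify_groups(
    z: np.ndarray,
    mode: str = "standard",
    lower: float = 1.0,
    inner: float = 0.5,
    split_at: float = 0.75,
) -> np.ndarray:
    """Band standardized residuals into UPC / EAC / UGC labels.

    mode="standard":   z<=-1 UPC, |z|<=0.5 EAC, z>=+1 UGC, else UNCLASSIFIED.
    mode="contiguous": the 0.5-1 SD shell joins EAC (EAC = -1 < z < 1).
    mode="split":      the shell splits outward at |z| >= split_at.
    NaN z (missing outcome) stays UNCLASSIFIED.
    """
    z = np.asarray(z, float)
    out = np.full(z.shape, UNCLASSIFIED, dtype=object)
    if mode == "standard":
        out[np.abs(z) <= inner] = EAC
    elif mode == "contiguous":
        out[np.abs(z) < lower] = EAC
    elif mode == "split":
        out[np.abs(z) < split_at] = EAC
        out[(z >= split_at) & (z < lower)] = UGC
        out[(z <= -split_at) & (z > -lower)] = UPC
    else:
        raise ValueError(f"unknown banding mode {mode!r}")
    out[z <= -lower] = UPC
    out[z >= lower] = UGC
    out[np.isnan(z)] = UNCLASSIFIED
    return out
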
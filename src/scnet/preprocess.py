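"""Covariate residualization of regional thickness.

Before building correlation networks, age, gender and age-by-gender effects
are removed region by region: for every region the best of five nested
linear models (chosen by AIC) is fitted on the pooled cohort and the
residuals replace the raw thickness values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

# Candidate models in increasing complexity; ties in AIC resolve to the
# earlier (smaller) model.
CANDIDATE_MODELS: tuple[tuple[str, ...], ...] = (
    ("intercept",),
    ("intercept", "age"),
    ("intercept", "gender"),
    ("intercept", "age", "gender"),
    ("intercept", "age", "gender", "age:gender"),
)


@dataclass
class ModelRecord:
    """Selected covariate model for one region."""

    terms: tuple[str, ...]
    aic: float
    coef: dict[str, float]
    candidate_aics: dict[str, float]


@dataclass
class ResidualMatrix:
    """Subjects x regions residual thickness plus per-region model records."""

    residuals: pd.DataFrame
    models: dict[str, ModelRecord]

    @property
    def region_labels(self) -> list[str]:
        return list(self.residuals.columns)

    @property
    def values(self) -> np.ndarray:
        return self.residuals.to_numpy(float)


def _design_columns(age: np.ndarray, male: np.ndarray) -> dict[str, np.ndarray]:
    return {
        "intercept": np.ones_like(age),
        "age": age,
        "gender": male,
        "age:gender": age * male,
    }


def _gaussian_aic(rss: float, n: int, n_coef: int) -> float:
    """Profile-likelihood AIC, n*ln(RSS/n) + 2k with k = coefficients + 1 (variance)."""
    rss = max(rss, 1e-300)  # guard the log for exact fits
    return n * np.log(rss / n) + 2 * (n_coef + 1)


def select_covariate_model(
    y: np.ndarray, age: np.ndarray, male: np.ndarray
) -> tuple[ModelRecord, np.ndarray]:
    """Fit the candidate models and return the minimum-AIC one with its residuals.

    Inestimable terms (rank-deficient design, e.g. a single-gender cohort)
    are dropped with a warning; ties in AIC break toward fewer parameters.
    """
    n = len(y)
    cols = _design_columns(age, male)
    best: tuple[float, int] | None = None
    best_rec: ModelRecord | None = None
    best_resid: np.ndarray | None = None
    cand_aics: dict[str, float] = {}

    for idx, terms in enumerate(CANDIDATE_MODELS):
        x = np.column_stack([cols[t] for t in terms])
        rank = np.linalg.matrix_rank(x)
        if rank < x.shape[1]:
            # drop trailing collinear terms, keep the estimable prefix
            keep = [0]
            for j in range(1, x.shape[1]):
                trial = x[:, keep + [j]]
                if np.linalg.matrix_rank(trial) == len(keep) + 1:
                    keep.append(j)
            dropped = [terms[j] for j in range(x.shape[1]) if j not in keep]
            warnings.warn(
                f"rank-deficient design: dropping inestimable terms {dropped}",
                stacklevel=2,
            )
            terms = tuple(terms[j] for j in keep)
            x = x[:, keep]
        if n <= x.shape[1]:
            continue
        beta, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ beta
        rss = float(resid @ resid)
        aic = _gaussian_aic(rss, n, x.shape[1])
        cand_aics["+".join(terms)] = aic
        if best is None or aic < best[0] - 1e-12:
            best = (aic, idx)
            best_rec = ModelRecord(
                terms=terms,
                aic=aic,
                coef=dict(zip(terms, map(float, beta))),
                candidate_aics={},
            )
            best_resid = resid
    if best_rec is None:
        raise ValueError("no candidate model is estimable (too few subjects)")
    best_rec.candidate_aics = cand_aics
    return best_rec, best_resid


def residualize_all(
    thickness: pd.DataFrame, age, gender
) -> ResidualMatrix:
    """Residualize every region independently over the full (pooled) cohort.

    ``gender`` may be 'M'/'F' strings or a 0/1 indicator (male = 1).
    Missing thickness or covariate values raise with the offending
    subject/region named.
    """
    if thickness.isna().any().any():
        stacked = thickness.isna().stack()
        subj, region = stacked[stacked].index[0]
        raise ValueError(f"missing thickness value at subject {subj!r}, region {region!r}")
    age = np.asarray(age, float)
    if np.isnan(age).any():
        raise ValueError("missing covariate: age contains NaN")
    gender = np.asarray(gender)
    if gender.dtype.kind in "OUS":
        bad = set(np.unique(gender)) - {"M", "F"}
        if bad:
            raise ValueError(f"missing or invalid gender values: {sorted(bad)}")
        male = (gender == "M").astype(float)
    else:
        male = np.asarray(gender, float)
        if np.isnan(male).any():
            raise ValueError("missing covariate: gender contains NaN")
    if len(age) != len(thickness) or len(male) != len(thickness):
        raise ValueError("covariate length does not match subject count")

    resid = np.empty(thickness.shape)
    models: dict[str, ModelRecord] = {}
    for j, region in enumerate(thickness.columns):
        rec, r = select_covariate_model(thickness.iloc[:, j].to_numpy(float), age, male)
        models[region] = rec
        resid[:, j] = r
    return ResidualMatrix(
        residuals=pd.DataFrame(resid, index=thickness.index, columns=thickness.columns),
        models=models,
    )
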
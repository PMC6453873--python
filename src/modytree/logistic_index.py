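"""Binary logistic regression and reduction to a composite biomarker index.

The diagnostic tree expresses each multi-marker step as a weighted linear
index in raw marker units — e.g. ``C-peptide [ng/ml] + 0.16 × BMI [kg/m²]``
— obtained by fitting a plain logistic regression (intercept + markers, no
transforms, no penalty) and dividing every coefficient by the lead marker's
coefficient so the lead weight is 1. The intercept is discarded: it shifts
every score equally and is absorbed into the decision threshold. Because the
index is a strictly monotone function of the fitted linear predictor, its
ROC curve and C-statistic are identical to the full model's.

Maximum likelihood is computed by iteratively reweighted least squares with
step-halving (so the deviance never increases between iterations) and
explicit detection of complete/quasi-complete separation, which is surfaced
as an error rather than silently producing huge coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort_model import Cohort, PatientRecord, marker_frame
from .exceptions import MissingMarkerError, SeparationError, SingularDesignError

__all__ = ["LogisticFit", "CompositeIndex", "fit_logistic", "index_from_fit", "evaluate_index"]

_DEVIANCE_TOL = 1e-8
_MAX_ITER = 100
_ETA_CLIP = 30.0  # |linear predictor| beyond this is numerically saturated


@dataclass(frozen=True)
class LogisticFit:
    """Maximum-likelihood logistic fit of outcome ~ intercept + markers."""

    markers: tuple[str, ...]
    coefficients: tuple[float, ...]  # per marker, same order
    intercept: float
    converged: bool
    n_iterations: int
    deviance: float
    standard_errors: tuple[float, ...] = ()  # (intercept, markers...) Wald SEs
    deviance_path: tuple[float, ...] = ()

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + X @ np.asarray(self.coefficients)


@dataclass(frozen=True)
class CompositeIndex:
    """Weighted marker sum ``Σ wᵢ·markerᵢ`` with the lead weight fixed at 1.

    ``direction`` records which side of the threshold is the positive call:
    ``higher_is_positive`` when the lead marker's logistic coefficient is
    positive, else ``lower_is_positive``.
    """

    markers: tuple[str, ...]
    weights: tuple[float, ...]
    direction: str = "higher_is_positive"
    threshold: float | None = None

    def __post_init__(self) -> None:
        if len(self.markers) != len(self.weights):
            raise ValueError("markers and weights must align")
        if len(set(self.markers)) != len(self.markers):
            raise ValueError("markers must be distinct")
        if not self.weights or self.weights[0] != 1.0:
            raise ValueError("the lead weight must be exactly 1")
        if self.direction not in ("higher_is_positive", "lower_is_positive"):
            raise ValueError(f"unknown direction {self.direction!r}")


def _design(data, markers: Sequence[str]) -> np.ndarray:
    if isinstance(data, (Cohort, list, tuple)):
        df = marker_frame(data, markers)
    else:
        df = pd.DataFrame(data)[list(markers)]
        if df.isna().any().any():
            bad = df.columns[df.isna().any()][0]
            raise MissingMarkerError(bad, "<frame>")
    return df.to_numpy(dtype=float)


def fit_logistic(data, outcome, markers: Sequence[str]) -> LogisticFit:
    """Fit outcome ~ intercept + markers by IRLS.

    ``data`` is a cohort, a sequence of records, or a data frame holding the
    marker columns; ``outcome`` is a 0/1 (or boolean) vector over the same
    rows. Convergence: deviance change < 1e-8, capped at 100 iterations.
    Raises :class:`SeparationError` on complete or quasi-complete separation
    and :class:`SingularDesignError` on a rank-deficient design.
    """
    markers = tuple(markers)
    X = _design(data, markers)
    y = np.asarray(outcome, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("outcome length does not match the number of records")
    n_pos = int(y.sum())
    if n_pos < 2 or y.size - n_pos < 2:
        raise ValueError("need at least 2 records per outcome class")
    Xd = np.column_stack([np.ones(X.shape[0]), X])
    if np.linalg.matrix_rank(Xd) < Xd.shape[1]:
        raise SingularDesignError(f"design matrix for markers {markers} is rank deficient")

    beta = np.zeros(Xd.shape[1])
    dev = _deviance(Xd, y, beta)
    path = [dev]
    converged = False
    it = 0
    for it in range(1, _MAX_ITER + 1):
        eta = np.clip(Xd @ beta, -_ETA_CLIP, _ETA_CLIP)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(p * (1.0 - p), 1e-10)
        z = eta + (y - p) / w
        sw = np.sqrt(w)
        try:
            step_target, *_ = np.linalg.lstsq(Xd * sw[:, None], z * sw, rcond=None)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
            raise SingularDesignError(str(exc)) from exc
        # step-halving keeps the deviance monotone non-increasing
        new_beta, new_dev = step_target, _deviance(Xd, y, step_target)
        frac = 1.0
        while new_dev > dev and frac > 1e-8:
            frac /= 2.0
            new_beta = beta + frac * (step_target - beta)
            new_dev = _deviance(Xd, y, new_beta)
        beta, prev_dev, dev = new_beta, dev, min(new_dev, dev)
        path.append(dev)
        if abs(prev_dev - dev) < _DEVIANCE_TOL:
            converged = True
            break

    _check_separation(Xd, y, beta, dev, markers)

    se = _wald_se(Xd, beta)
    return LogisticFit(
        markers=markers,
        coefficients=tuple(float(b) for b in beta[1:]),
        intercept=float(beta[0]),
        converged=converged,
        n_iterations=it,
        deviance=float(dev),
        standard_errors=tuple(float(s) for s in se),
        deviance_path=tuple(path),
    )


def _deviance(Xd: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = Xd @ beta
    # numerically stable -2·loglik: log(1+e^eta) - y·eta
    return float(2.0 * np.sum(np.logaddexp(0.0, eta) - y * eta))


def _check_separation(Xd, y, beta, dev, markers) -> None:
    eta = Xd @ beta
    p = 1.0 / (1.0 + np.exp(-np.clip(eta, -_ETA_CLIP, _ETA_CLIP)))
    perfect = np.all((p > 0.5) == (y > 0.5)) and np.all(np.abs(y - p) < 1e-4)
    if perfect and dev < 1e-6 * max(1, y.size):
        raise SeparationError(markers, "complete separation: deviance collapsed to 0")
    scale = np.max(np.abs(Xd), axis=0)
    if np.any(np.abs(beta) * np.maximum(scale, 1e-12) > 1e4):
        raise SeparationError(markers, "quasi-complete separation: diverging coefficients")


def _wald_se(Xd: np.ndarray, beta: np.ndarray) -> np.ndarray:
    eta = np.clip(Xd @ beta, -_ETA_CLIP, _ETA_CLIP)
    p = 1.0 / (1.0 + np.exp(-eta))
    w = np.maximum(p * (1.0 - p), 1e-10)
    info = (Xd * w[:, None]).T @ Xd
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:  # pragma: no cover - defensive
        return np.full(beta.size, np.nan)
    return np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))


def index_from_fit(fit: LogisticFit) -> CompositeIndex:
    """Reduce a converged fit to the weight-1-lead composite index.

    Weights are the coefficients divided by the lead marker's coefficient;
    the sign of the lead coefficient sets the direction and the intercept is
    absorbed into the (later-chosen) threshold.
    """
    if not fit.converged:
        raise ValueError("refusing to build an index from a non-converged fit")
    lead = fit.coefficients[0]
    if lead == 0.0:
        raise ValueError(f"lead marker {fit.markers[0]!r} has zero coefficient")
    weights = tuple(float(c / lead) for c in fit.coefficients)
    direction = "higher_is_positive" if lead > 0 else "lower_is_positive"
    return CompositeIndex(markers=fit.markers, weights=weights, direction=direction)


def evaluate_index(index: CompositeIndex, record: PatientRecord) -> float:
    """Index score ``Σ wᵢ·markerᵢ`` for one record, in raw marker units."""
    total = 0.0
    for m, w in zip(index.markers, index.weights):
        v = getattr(record, m, None)
        if v is None:
            raise MissingMarkerError(m, record.id)
        total += w * float(v)
    return total


def evaluate_index_frame(index: CompositeIndex, df: pd.DataFrame) -> np.ndarray:
    """Vectorized index scores over a marker data frame."""
    X = _design(df, index.markers)
    return X @ np.asarray(index.weights)
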
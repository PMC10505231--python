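"""Logistic fusion of the two arm-level fold-change estimates.

Clinically, 1p and 19q FISH results are read jointly: codeletion of both
arms defines oligodendroglioma. The fusion step mirrors that by feeding
the two slide-level FC estimates into a logistic regression —
``P(oligodendroglioma) = sigmoid(b0 + b1 * fc_1p + b2 * fc_19q)`` —
trained with binary cross-entropy. Because lower FC means deletion, a
well-fitted model has negative coefficients for both arms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression

from .bags import sigmoid
from .synthetic import TumorType


@dataclass
class LogisticParams:
    coef_1p: float
    coef_19q: float
    intercept: float
    cutoff: float = 0.5

    def __post_init__(self) -> None:
        for name in ("coef_1p", "coef_19q", "intercept", "cutoff"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"non-finite {name}")


def train_logistic(fc_pairs, labels, seed: int = 0) -> LogisticParams:
    """Fit the fusion model by (lightly L2-stabilized) maximum likelihood.

    ``labels`` encode oligodendroglioma as 1. A vanishing penalty
    (lambda = 1e-6) keeps the fit finite on perfectly separable cohorts.
    """
    X = np.asarray(fc_pairs, dtype=np.float64)
    y = np.asarray(labels, dtype=np.int64)
    if X.ndim != 2 or X.shape[1] != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("fc_pairs must be (n, 2) with one binary label per row")
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate fit: both classes must be present")
    model = LogisticRegression(
        C=1e6,  # L2 with lambda = 1e-6
        tol=1e-10,
        max_iter=100_000,
        random_state=seed,
    )
    model.fit(X, y)
    return LogisticParams(
        coef_1p=float(model.coef_[0, 0]),
        coef_19q=float(model.coef_[0, 1]),
        intercept=float(model.intercept_[0]),
    )


def predict_proba(fc_1p: float, fc_19q: float, params: LogisticParams) -> float:
    """Oligodendroglioma probability for one slide's FC pair."""
    if not (np.isfinite(fc_1p) and np.isfinite(fc_19q)):
        raise ValueError("FC inputs must be finite")
    return sigmoid(params.intercept + params.coef_1p * fc_1p + params.coef_19q * fc_19q)


def classify(prob: float, cutoff: float = 0.5) -> TumorType:
    """Threshold the fused probability; ties at the cutoff go to
    oligodendroglioma (``>=``)."""
    if not (0.0 < cutoff < 1.0):
        raise ValueError("cutoff must lie in the open interval (0, 1)")
    if not (0.0 <= prob <= 1.0):
        raise ValueError("prob must lie in [0, 1]")
    return TumorType.OLIGODENDROGLIOMA if prob >= cutoff else TumorType.ASTROCYTOMA
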
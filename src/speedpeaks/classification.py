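"""Logistic classification in the one-dimensional R space.

The model is ``P(positive | R) = sigmoid(slope * R + intercept)`` fitted by
unregularized maximum likelihood; the positive class is the high-R (mature)
group. Includes the repeated 70/30 split evaluation protocol.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from .errors import SpeedPeaksError

__all__ = [
    "LogisticModel",
    "fit_logistic",
    "predict",
    "decision_boundary",
    "SplitEvaluation",
    "split_evaluate",
]

log = logging.getLogger("speedpeaks.classification")

GRAD_TOL = 1e-8


@dataclass(frozen=True)
class LogisticModel:
    slope: float
    intercept: float
    converged: bool = True
    perfectly_separated: bool = False
    positive_class: object = 1


def _nll_and_grad(params: np.ndarray, r: np.ndarray, y: np.ndarray):
    z = params[0] * r + params[1]
    # log(1 + exp(-z*y_pm)) with y_pm = +-1, numerically stable
    y_pm = 2.0 * y - 1.0
    nll = float(np.sum(np.logaddexp(0.0, -y_pm * z)))
    p = expit(z)
    resid = p - y
    grad = np.array([np.sum(resid * r), np.sum(resid)])
    return nll, grad


def fit_logistic(r_values: np.ndarray, labels: np.ndarray) -> LogisticModel:
    """Unregularized maximum-likelihood logistic fit of labels on R.

    ``labels`` must contain exactly two values; the larger one (after
    sorting) is the positive class. Converges to gradient norm below 1e-8
    or raises the perfect-separation flag with a warning.
    """
    r = np.asarray(r_values, dtype=float)
    labels = np.asarray(labels)
    if r.ndim != 1 or r.shape != labels.shape:
        raise SpeedPeaksError("r_values and labels must be equal-length 1-D")
    if not np.all(np.isfinite(r)):
        raise SpeedPeaksError("r_values must be finite")
    classes = np.unique(labels)
    if classes.size != 2:
        raise SpeedPeaksError(
            f"exactly 2 classes required, got {classes.size}"
        )
    positive = classes[-1]
    y = (labels == positive).astype(float)

    res = minimize(
        _nll_and_grad,
        x0=np.zeros(2),
        args=(r, y),
        jac=True,
        method="BFGS",
        options={"gtol": GRAD_TOL / 10, "maxiter": 5000},
    )
    params = res.x
    _, grad = _nll_and_grad(params, r, y)
    # BFGS can stall on precision loss just above the tolerance; the 2x2
    # Hessian is analytic, so polish with a few Newton steps
    for _ in range(50):
        if np.linalg.norm(grad) < GRAD_TOL:
            break
        p = expit(params[0] * r + params[1])
        w = p * (1.0 - p)
        hess = np.array(
            [[np.sum(w * r * r), np.sum(w * r)], [np.sum(w * r), np.sum(w)]]
        )
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        if not np.all(np.isfinite(step)):
            break
        params = params - step
        _, grad = _nll_and_grad(params, r, y)
    slope, intercept = params
    grad_norm = float(np.linalg.norm(grad))
    converged = grad_norm < GRAD_TOL
    separated = False
    if not converged:
        p = expit(slope * r + intercept)
        if np.all((p >= 0.5) == (y == 1.0)):
            separated = True
            log.warning(
                "perfect separation: likelihood unbounded, coefficients "
                "diverge (|grad| = %.3g)",
                grad_norm,
            )
        else:
            log.warning("logistic fit did not converge (|grad| = %.3g)", grad_norm)
    return LogisticModel(
        slope=float(slope),
        intercept=float(intercept),
        converged=converged,
        perfectly_separated=separated,
        positive_class=positive,
    )


def predict(model: LogisticModel, R) -> tuple[np.ndarray, np.ndarray]:
    """Probability of the positive class and the 0.5-threshold label."""
    r = np.asarray(R, dtype=float)
    prob = expit(model.slope * r + model.intercept)
    label = prob >= 0.5
    return prob, label


def decision_boundary(model: LogisticModel) -> float:
    """R value where the predicted probability crosses 0.5 (frames)."""
    if model.slope == 0:
        raise SpeedPeaksError("zero slope: decision boundary undefined")
    return -model.intercept / model.slope


@dataclass(frozen=True)
class SplitEvaluation:
    mean_train_accuracy: float
    mean_test_accuracy: float
    per_iteration: pd.DataFrame


def split_evaluate(
    r_values: np.ndarray,
    labels: np.ndarray,
    train_frac: float = 0.7,
    iters: int = 50,
    seed: int = 0,
    max_retries: int = 1000,
) -> SplitEvaluation:
    """Repeated random train/test splits with per-split refits.

    Each iteration draws a ``train_frac`` split (redrawn, with logging,
    until both classes appear in the training set), refits the model and
    scores accuracy on both sides. Deterministic given ``seed``.
    """
    r = np.asarray(r_values, dtype=float)
    labels = np.asarray(labels)
    n = r.size
    n_train = int(round(train_frac * n))
    if not 0 < n_train < n:
        raise SpeedPeaksError("train_frac leaves an empty train or test set")
    rng = np.random.default_rng(seed)
    rows = []
    for it in range(iters):
        for attempt in range(max_retries):
            perm = rng.permutation(n)
            tr, te = perm[:n_train], perm[n_train:]
            if np.unique(labels[tr]).size == 2:
                if attempt:
                    log.info("iteration %d: resampled %d time(s)", it, attempt)
                break
        else:
            raise SpeedPeaksError(
                "could not draw a training split containing both classes"
            )
        model = fit_logistic(r[tr], labels[tr])
        _, pred_tr = predict(model, r[tr])
        _, pred_te = predict(model, r[te])
        acc_tr = float(np.mean(pred_tr == (labels[tr] == model.positive_class)))
        acc_te = float(np.mean(pred_te == (labels[te] == model.positive_class)))
        rows.append(
            {
                "iteration": it,
                "train_accuracy": acc_tr,
                "test_accuracy": acc_te,
                "slope": model.slope,
                "intercept": model.intercept,
            }
        )
    df = pd.DataFrame(rows)
    return SplitEvaluation(
        mean_train_accuracy=float(df["train_accuracy"].mean()),
        mean_test_accuracy=float(df["test_accuracy"].mean()),
        per_iteration=df,
    )
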
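"""Penalized multinomial logistic regression on marker z-scores.

Disease groups sharing a metabolic pathway are discriminated with a
multinomial logit over the z-scores of every established marker for the
group (markers are kept regardless of univariate significance).  The
model uses a reference-class parameterization: the first declared class
(conventionally ``control``) has a zero coefficient row, and each other
class k has a linear predictor

    eta_k = beta_k0 + sum_j beta_kj * z_j

with class probabilities given by the softmax over (0, eta_2, ...).

Because disease cohorts are small and markers are strongly diagnostic,
quasi-complete separation is the norm; an L2 penalty on the
non-intercept coefficients (default 0.01) keeps the optimum finite and
reproducible while leaving the decision boundary essentially unchanged.
The penalized negative log-likelihood is strictly convex, so the
L-BFGS optimum is the unique global one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special

__all__ = [
    "DEFAULT_L2_PENALTY",
    "OR_REPORT_BOUND",
    "MLRModel",
    "fit_mlr",
    "linear_predictors",
    "predict",
    "odds_ratios",
    "confusion_matrix",
]

DEFAULT_L2_PENALTY = 0.01

#: Odds ratios beyond ~1/999 .. 999 are flagged as outside the
#: reportable analytical range.
OR_REPORT_BOUND = float(np.log(999.0))


@dataclass
class MLRModel:
    """Fitted multinomial logit.

    ``coef`` has one row per class (classes x (1 + markers), first
    column intercept); the reference-class row is identically zero.
    """

    classes: tuple[str, ...]
    markers: tuple[str, ...]
    coef: np.ndarray
    l2_penalty: float
    reference_class: str

    def __post_init__(self) -> None:
        self.coef = np.asarray(self.coef, dtype=float)
        if self.coef.shape != (len(self.classes), 1 + len(self.markers)):
            raise ValueError("coefficient matrix shape mismatch")
        if not np.all(np.isfinite(self.coef)):
            raise ValueError("non-finite coefficients")
        ref = self.classes.index(self.reference_class)
        if not np.all(self.coef[ref] == 0):
            raise ValueError("reference-class row must be zero")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "classes": list(self.classes),
                    "markers": list(self.markers),
                    "coef": self.coef.tolist(),
                    "l2_penalty": self.l2_penalty,
                    "reference_class": self.reference_class,
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "MLRModel":
        d = json.loads(Path(path).read_text())
        return cls(
            classes=tuple(d["classes"]),
            markers=tuple(d["markers"]),
            coef=np.array(d["coef"], dtype=float),
            l2_penalty=float(d["l2_penalty"]),
            reference_class=d["reference_class"],
        )


def _design(z: pd.DataFrame, markers: Sequence[str]) -> np.ndarray:
    missing = [m for m in markers if m not in z.columns]
    if missing:
        raise ValueError(f"markers missing from z matrix: {missing}")
    X = z[list(markers)].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("missing marker values")
    return np.hstack([np.ones((len(X), 1)), X])


def fit_mlr(
    z: pd.DataFrame,
    labels: Sequence[str],
    markers: Sequence[str],
    l2_penalty: float = DEFAULT_L2_PENALTY,
    classes: Sequence[str] | None = None,
    max_iter: int = 2000,
) -> MLRModel:
    """Maximize the multinomial log-likelihood minus an L2 penalty on
    the non-intercept coefficients.

    The first class in ``classes`` (declared order; defaults to sorted
    labels with ``control`` first) is the reference.  Deterministic:
    zero initialization, fixed solver.  With ``l2_penalty=0`` and
    separable data, divergence is reported as non-convergence.
    """
    markers = tuple(markers)
    if len(set(markers)) != len(markers):
        raise ValueError("duplicate (collinear) markers in marker list")
    if l2_penalty < 0:
        raise ValueError("l2_penalty must be non-negative")
    y_raw = np.asarray(list(labels))
    if classes is None:
        uniq = sorted(set(y_raw))
        if "control" in uniq:
            uniq.remove("control")
            uniq = ["control"] + uniq
        classes = uniq
    classes = tuple(classes)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    unknown = set(y_raw) - set(classes)
    if unknown:
        raise ValueError(f"labels outside declared classes: {sorted(unknown)}")
    for c in classes:
        if not np.any(y_raw == c):
            raise ValueError(f"class {c!r} has no samples")

    X = _design(z, markers)
    n, p = X.shape
    K = len(classes)
    y = np.array([classes.index(c) for c in y_raw])
    Y = np.zeros((n, K))
    Y[np.arange(n), y] = 1.0

    def unpack(theta: np.ndarray) -> np.ndarray:
        B = np.zeros((K, p))
        B[1:] = theta.reshape(K - 1, p)
        return B

    def objective(theta: np.ndarray) -> tuple[float, np.ndarray]:
        B = unpack(theta)
        eta = X @ B.T  # n x K, reference column = 0
        log_prob = eta - special.logsumexp(eta, axis=1, keepdims=True)
        nll = -float(np.sum(log_prob[np.arange(n), y]))
        pen = 0.5 * l2_penalty * float(np.sum(B[:, 1:] ** 2))
        P = np.exp(log_prob)
        G = (P - Y).T @ X  # K x p
        G[:, 1:] += l2_penalty * B[:, 1:]
        return nll + pen, G[1:].ravel()

    theta0 = np.zeros((K - 1) * p)
    res = optimize.minimize(
        objective,
        theta0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": 1e-8, "ftol": 1e-12},
    )
    grad_norm = float(np.max(np.abs(res.jac)))
    # With a positive penalty the problem is strictly convex; demand a
    # stationary point.  Without one, separation drives coefficients to
    # infinity and the gradient cannot vanish.
    if grad_norm > 1e-3 * max(1.0, float(np.abs(res.fun))):
        raise RuntimeError(
            f"MLR did not converge (max |gradient| = {grad_norm:.3g})"
        )
    # Under separation with no penalty the likelihood has no finite
    # optimum: coefficients run off while the gradient decays, so detect
    # divergence by magnitude instead.
    if l2_penalty == 0 and np.max(np.abs(res.x)) > 30.0:
        raise RuntimeError(
            "MLR did not converge: coefficients diverged "
            f"(max |gradient| = {grad_norm:.3g}); separated data with "
            "l2_penalty=0 has no finite optimum"
        )
    return MLRModel(
        classes=classes,
        markers=markers,
        coef=unpack(res.x),
        l2_penalty=float(l2_penalty),
        reference_class=classes[0],
    )


def linear_predictors(model: MLRModel, z_row: pd.Series | dict) -> pd.Series:
    """Per-class linear predictors for one sample (reference class 0)."""
    row = pd.Series(z_row)
    missing = [m for m in model.markers if m not in row.index or pd.isna(row[m])]
    if missing:
        raise ValueError(f"missing marker values: {missing}")
    x = np.concatenate([[1.0], row[list(model.markers)].to_numpy(dtype=float)])
    return pd.Series(model.coef @ x, index=list(model.classes))


def predict(
    model: MLRModel, z_row: pd.Series | dict
) -> tuple[str, pd.Series]:
    """Softmax class probabilities and the argmax label (ties broken by
    declared class order)."""
    eta = linear_predictors(model, z_row)
    p = np.exp(eta - special.logsumexp(eta.to_numpy()))
    probs = pd.Series(p, index=eta.index)
    return str(probs.index[int(np.argmax(probs.to_numpy()))]), probs


def predict_table(model: MLRModel, z: pd.DataFrame) -> pd.Series:
    """Vectorized argmax prediction for a z matrix."""
    X = _design(z, model.markers)
    eta = X @ model.coef.T
    order = np.argmax(eta, axis=1)
    return pd.Series([model.classes[i] for i in order], index=z.index)


def odds_ratios(model: MLRModel) -> pd.DataFrame:
    """exp(beta) per non-reference class and marker, flagged when |beta|
    exceeds ln(999) (beyond the reportable range)."""
    rows = []
    for ci, cls in enumerate(model.classes):
        if cls == model.reference_class:
            continue
        for mi, marker in enumerate(model.markers, start=1):
            beta = model.coef[ci, mi]
            rows.append(
                {
                    "class": cls,
                    "marker": marker,
                    "beta": beta,
                    "odds_ratio": float(np.exp(beta)),
                    "beyond_range": bool(abs(beta) > OR_REPORT_BOUND),
                }
            )
    return pd.DataFrame(rows)


def confusion_matrix(
    predicted: Sequence[str],
    actual: Sequence[str],
    classes: Sequence[str],
) -> pd.DataFrame:
    """Actual x predicted counts over the declared classes."""
    pred = list(predicted)
    act = list(actual)
    if len(pred) != len(act):
        raise ValueError("predicted/actual length mismatch")
    classes = list(classes)
    bad = (set(pred) | set(act)) - set(classes)
    if bad:
        raise ValueError(f"labels outside model classes: {sorted(bad)}")
    mat = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for a, p in zip(act, pred):
        mat.loc[a, p] += 1
    mat.index.name = "actual"
    mat.columns.name = "predicted"
    return mat
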
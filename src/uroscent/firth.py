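"""Firth bias-reduced logistic regression.

Maximizes the Jeffreys-penalized log-likelihood

    l*(beta) = l(beta) + 0.5 * log det I(beta),

where ``I`` is the Fisher information ``X' W X``.  The penalty removes the
O(1/n) bias of the MLE and keeps every coefficient finite even under
complete separation, which is why it is the standard final fit for small
case/control studies with near-separable predictors.  Solved by Newton
iterations on the modified score

    U*_j = sum_i (y_i - p_i + h_i (1/2 - p_i)) x_ij,

with ``h_i`` the hat values of the weighted design, and step-halving on
the penalized likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import ValidationError


@dataclass
class LogisticFit:
    """A fitted logistic model (penalized or Firth)."""

    intercept: float
    coefficients: np.ndarray
    feature_names: list[str]
    method: str
    converged: bool = True
    tuning_parameter: float | None = None
    selected_set: list[str] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.intercept + X @ self.coefficients

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return _sigmoid(self.linear_predictor(X))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -35.0, 35.0)))


def _penalized_loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    p = _sigmoid(eta)
    ll = float(y @ np.log(np.clip(p, 1e-12, None))
               + (1 - y) @ np.log(np.clip(1 - p, 1e-12, None)))
    w = p * (1 - p)
    info = (X * w[:, None]).T @ X
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0:
        return -np.inf
    return ll + 0.5 * logdet


def firth_fit(
    design: np.ndarray,
    labels: np.ndarray,
    feature_names: list[str] | None = None,
    add_intercept: bool = True,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> LogisticFit:
    """Fit a Firth-penalized logistic regression.

    ``design`` is the predictor matrix (without intercept column unless
    ``add_intercept=False``); ``labels`` are 0/1 or cohort strings.  For an
    intercept-only model the estimate has the closed form
    ``logit((s + 1/2) / (n + 1))`` with ``s`` successes of ``n``.
    """
    X = np.asarray(design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = _as_binary(labels)
    if X.shape[0] != y.size:
        raise ValidationError("design and labels differ in length")
    if not np.all(np.isfinite(X)):
        raise ValidationError("design matrix must be finite")
    flags = []
    if X.shape[0] < X.shape[1] + int(add_intercept):
        flags.append("n_less_than_p")

    if add_intercept:
        X = np.hstack([np.ones((X.shape[0], 1)), X])
    n, p = X.shape
    beta = np.zeros(p)

    for _ in range(max_iter):
        eta = X @ beta
        prob = _sigmoid(eta)
        w = np.clip(prob * (1 - prob), 1e-10, None)
        Xw = X * np.sqrt(w)[:, None]
        info = Xw.T @ Xw
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            info_inv = np.linalg.inv(info + 1e-6 * np.eye(p))
            flags.append("singular_information_ridge")
        # hat values of the weighted design
        h = np.einsum("ij,jk,ik->i", Xw, info_inv, Xw)
        score = X.T @ (y - prob + h * (0.5 - prob))
        if np.linalg.norm(score, ord=np.inf) < tol:
            break
        step = info_inv @ score
        # step-halving on the penalized likelihood
        ll0 = _penalized_loglik(X, y, beta)
        scale = 1.0
        for _half in range(20):
            cand = beta + scale * step
            if _penalized_loglik(X, y, cand) >= ll0 - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
    else:
        flags.append("max_iter_reached")

    converged = "max_iter_reached" not in flags
    if add_intercept:
        intercept, coefs = float(beta[0]), beta[1:]
    else:
        intercept, coefs = 0.0, beta
    names = feature_names or [f"x{i + 1}" for i in range(coefs.size)]
    return LogisticFit(
        intercept=intercept,
        coefficients=coefs,
        feature_names=list(names),
        method="firth",
        converged=converged,
        selected_set=list(names),
        flags=sorted(set(flags)),
    )


def _as_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype == object or labels.dtype.kind in "US":
        return (np.asarray(labels, dtype=object) == "cancer").astype(float)
    y = np.asarray(labels, dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValidationError("labels must be binary or cancer/control strings")
    return y
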
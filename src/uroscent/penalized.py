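"""Sure-independence screening with concave-penalized logistic regression.

The high-dimensional model-building step: marginal-utility ranking (SIS)
cuts the screened compounds to at most ``n / log(n)``, then a sparse
logistic model is fitted with a folded-concave penalty (SCAD by default;
MCP and lasso available) by local linear approximation (LLA) around a
lasso initializer, with a glmnet-style IRLS + coordinate-descent inner
solver.  The tuning parameter is chosen by stratified k-fold
cross-validated deviance.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from numba import njit

from .config import ValidationError
from .containers import VocTable
from .firth import LogisticFit, _as_binary, _sigmoid

PENALTIES = ("scad", "mcp", "lasso")


def sis_rank(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Rank features by absolute standardized marginal association.

    Equivalent to the one-step marginal logistic coefficient on
    standardized predictors: features are ordered by
    ``|x_std' (y - ybar)|``, largest first.
    """
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=0)
    sd[sd == 0] = np.inf  # constant features rank last
    score = np.abs((X - X.mean(axis=0)).T @ (y - y.mean())) / sd
    return np.argsort(-score, kind="stable")


def sis_cap(n_samples: int) -> int:
    return max(1, int(np.floor(n_samples / math.log(n_samples))))


def _penalty_deriv(t: np.ndarray, lam: float, penalty: str, a: float) -> np.ndarray:
    """Derivative p'_lambda(|t|) of the chosen penalty (LLA weights)."""
    t = np.abs(t)
    if penalty == "lasso":
        return np.full_like(t, lam)
    if penalty == "scad":
        out = np.where(t <= lam, lam, np.maximum(a * lam - t, 0.0) / (a - 1.0))
        return out
    if penalty == "mcp":
        return np.maximum(lam - t / a, 0.0)
    raise ValidationError(f"penalty must be one of {PENALTIES}")


@njit(cache=True)
def _cd_core(X, y, pen_weights, beta0, beta, max_irls, max_sweeps, tol):
    """Weighted-L1 logistic: IRLS outer loop, coordinate-descent inner loop.

    ``pen_weights`` are per-feature L1 weights (an LLA linearization of the
    concave penalty).  Mutates ``beta`` in place; returns (intercept,
    converged flag).
    """
    n, p = X.shape
    converged = False
    r = np.empty(n)
    for _irls in range(max_irls):
        old0 = beta0
        old = beta.copy()
        # IRLS working response and weights
        w = np.empty(n)
        for i in range(n):
            eta = beta0
            for j in range(p):
                eta += X[i, j] * beta[j]
            prob = 1.0 / (1.0 + np.exp(-min(max(eta, -35.0), 35.0)))
            wi = prob * (1.0 - prob)
            if wi < 1e-5:
                wi = 1e-5
            w[i] = wi
            r[i] = (eta + (y[i] - prob) / wi) - eta  # residual of z around eta
        wsum = w.sum()
        denom = np.empty(p)
        for j in range(p):
            s = 0.0
            for i in range(n):
                s += w[i] * X[i, j] * X[i, j]
            denom[j] = s / n

        # one full sweep, then active-set cycles with a closing full sweep
        for _cycle in range(5):
            full = _cycle == 0
            for _sweep in range(max_sweeps):
                max_delta = 0.0
                for j in range(p):
                    if not full and beta[j] == 0.0:
                        continue
                    bj_old = beta[j]
                    rho = 0.0
                    for i in range(n):
                        rho += w[i] * X[i, j] * (r[i] + X[i, j] * bj_old)
                    rho /= n
                    lam_j = pen_weights[j]
                    if rho > lam_j:
                        bj = (rho - lam_j) / denom[j]
                    elif rho < -lam_j:
                        bj = (rho + lam_j) / denom[j]
                    else:
                        bj = 0.0
                    if bj != bj_old:
                        d = abs(bj - bj_old)
                        if d > max_delta:
                            max_delta = d
                        beta[j] = bj
                        for i in range(n):
                            r[i] += X[i, j] * (bj_old - bj)
                b0_delta = 0.0
                for i in range(n):
                    b0_delta += w[i] * r[i]
                b0_delta /= wsum
                beta0 += b0_delta
                for i in range(n):
                    r[i] -= b0_delta
                if abs(b0_delta) > max_delta:
                    max_delta = abs(b0_delta)
                if max_delta < tol:
                    break
                full = False  # after first pass restrict to active set
            # closing full sweep: check for violated zero coordinates
            changed = False
            for j in range(p):
                if beta[j] != 0.0:
                    continue
                rho = 0.0
                for i in range(n):
                    rho += w[i] * X[i, j] * r[i]
                rho /= n
                if abs(rho) > pen_weights[j] + tol:
                    changed = True
                    break
            if not changed:
                break

        diff = abs(beta0 - old0)
        for j in range(p):
            if abs(beta[j] - old[j]) > diff:
                diff = abs(beta[j] - old[j])
        if diff < 1e-5:
            converged = True
            break
    return beta0, converged


def _cd_weighted_lasso(
    X: np.ndarray,
    y: np.ndarray,
    pen_weights: np.ndarray,
    beta0: float,
    beta: np.ndarray,
    max_irls: int = 6,
    max_sweeps: int = 25,
    tol: float = 1e-5,
) -> tuple[float, np.ndarray, bool]:
    beta = np.ascontiguousarray(beta, dtype=np.float64)
    beta0, converged = _cd_core(
        np.ascontiguousarray(X, dtype=np.float64),
        np.ascontiguousarray(y, dtype=np.float64),
        np.ascontiguousarray(pen_weights, dtype=np.float64),
        float(beta0), beta, max_irls, max_sweeps, tol,
    )
    return float(beta0), beta, bool(converged)


def _fit_concave(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    penalty: str = "scad",
    a: float | None = None,
    n_lla: int = 3,
    warm: tuple[float, np.ndarray] | None = None,
) -> tuple[float, np.ndarray, bool]:
    """One penalized fit at a fixed lambda on standardized X."""
    if a is None:
        a = 3.7 if penalty == "scad" else 3.0
    p = X.shape[1]
    if warm is not None:
        beta0, beta = warm[0], warm[1].copy()
    else:
        beta0 = float(np.log(y.mean() / (1 - y.mean()))) if 0 < y.mean() < 1 else 0.0
        beta = np.zeros(p)
    ok = True
    # LLA: first pass is plain lasso (weights = lambda), then reweighted
    for it in range(n_lla if penalty != "lasso" else 1):
        pen_w = _penalty_deriv(beta, lam, penalty, a) if it else np.full(p, lam)
        beta0, beta, ok = _cd_weighted_lasso(X, y, pen_w, beta0, beta)
    return beta0, beta, ok


def _fit_path(
    X: np.ndarray,
    y: np.ndarray,
    lambdas: np.ndarray,
    penalty: str,
) -> list[tuple[float, np.ndarray, bool]]:
    """Fit the whole (descending) lambda path with warm starts."""
    fits = []
    warm = None
    for li, lam in enumerate(lambdas):
        n_lla = 3 if warm is None else 2
        b0, b, ok = _fit_concave(X, y, lam, penalty, n_lla=n_lla, warm=warm)
        fits.append((b0, b, ok))
        warm = (b0, b)
    return fits


def _deviance(y: np.ndarray, prob: np.ndarray) -> float:
    prob = np.clip(prob, 1e-8, 1 - 1e-8)
    return float(-2.0 * (y @ np.log(prob) + (1 - y) @ np.log(1 - prob)))


def _stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Fold assignment balancing the two classes across folds."""
    assign = np.empty(y.size, dtype=int)
    for cls in (0.0, 1.0):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        assign[idx] = np.arange(idx.size) % k
    return assign


def fit_penalized_logistic(
    table: VocTable | np.ndarray,
    labels: np.ndarray | None = None,
    folds: int = 10,
    seed: int = 0,
    penalty: str = "scad",
    feature_names: list[str] | None = None,
    n_lambda: int = 12,
    lambda_min_ratio: float = 0.02,
    sis_max: int | None = None,
) -> LogisticFit:
    """Two-stage sparse logistic fit: SIS ranking then a concave penalty.

    Features are first cut to at most ``n/log(n)`` (or ``sis_max``) by
    marginal ranking, then a SCAD/MCP/lasso-penalized logistic model is
    fitted along a lambda path, with the tuning parameter chosen by
    ``folds``-fold stratified cross-validated deviance.  Coefficients are
    returned on the original predictor scale; the selected set is the
    support of the fit at the chosen lambda.
    """
    if isinstance(table, VocTable):
        X_raw = table.abundances
        names = list(table.compound_ids)
        y = _as_binary(table.labels)
    else:
        X_raw = np.asarray(table, dtype=float)
        y = _as_binary(labels)
        names = list(feature_names) if feature_names else [
            f"x{i + 1}" for i in range(X_raw.shape[1])
        ]
    n = X_raw.shape[0]
    if folds < 2:
        raise ValidationError("folds must be at least 2")
    if n < folds:
        raise ValidationError("need at least as many samples as folds")
    if penalty not in PENALTIES:
        raise ValidationError(f"penalty must be one of {PENALTIES}")

    cap = sis_cap(n) if sis_max is None else sis_max
    order = sis_rank(X_raw, y)[: min(cap, X_raw.shape[1])]
    X_sub = X_raw[:, order]
    mu, sd = X_sub.mean(axis=0), X_sub.std(axis=0)
    sd[sd == 0] = 1.0
    X = (X_sub - mu) / sd

    lam_max = float(np.max(np.abs(X.T @ (y - y.mean()))) / n)
    lam_max = max(lam_max, 1e-4)
    lambdas = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)

    rng = np.random.default_rng(seed)
    assign = _stratified_folds(y, folds, rng)
    cv_dev = np.zeros(n_lambda)
    for k in range(folds):
        tr, te = assign != k, assign == k
        if len(np.unique(y[tr])) < 2:
            warnings.warn(f"fold {k} lost a class; skipped")
            continue
        for li, (b0, b, _) in enumerate(_fit_path(X[tr], y[tr], lambdas, penalty)):
            prob = _sigmoid(b0 + X[te] @ b)
            cv_dev[li] += _deviance(y[te], prob)
    best = int(np.argmin(cv_dev))
    lam_star = float(lambdas[best])

    b0, b, ok = _fit_path(X, y, lambdas[: best + 1], penalty)[-1]
    support = np.flatnonzero(b != 0.0)
    coefs_orig = b / sd
    intercept = b0 - float((coefs_orig * mu).sum())

    sel_names = [names[order[j]] for j in support]
    flags = [] if ok else ["inner_solver_not_converged"]
    fit = LogisticFit(
        intercept=intercept,
        coefficients=coefs_orig,
        feature_names=[names[j] for j in order],
        method="penalized",
        converged=ok,
        tuning_parameter=lam_star,
        selected_set=sel_names,
        flags=flags,
    )
    return fit
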
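"""GC-MS volatilome statistics: screening and honest model evaluation.

The chain mirrors a small-sample, high-dimensional VOC study: compounds
observed in under a minimum fraction of samples are removed, the remainder
are screened with the Wilcoxon rank-sum test (robust to zero inflation),
a liberal p-value cutoff feeds a sure-independence-screening plus
concave-penalized logistic model tuned by cross-validation, the final
model is refitted by Firth bias-reduced logistic regression, and
performance is assessed by jackknife (leave-one-out) prediction — with
screening, selection, and refit all repeated inside every fold so the
reported ROC is not inflated by variable selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import mannwhitneyu, tiecorrect
from sklearn.metrics import roc_curve as _sk_roc_curve

from .config import ValidationError
from .containers import VocTable
from .firth import LogisticFit, _as_binary, firth_fit
from .penalized import fit_penalized_logistic


def prevalence_filter(table: VocTable, min_prevalence: float = 0.03) -> VocTable:
    """Drop compounds observed (nonzero) in fewer than the minimum fraction.

    A compound is retained when its nonzero count is at least
    ``ceil(min_prevalence * n_samples)``; samples are never dropped.
    """
    if not 0.0 < min_prevalence < 1.0:
        raise ValidationError("min_prevalence must lie in (0, 1)")
    if table.n_samples == 0 or table.n_compounds == 0:
        raise ValidationError("cannot filter an empty table")
    need = int(np.ceil(min_prevalence * table.n_samples))
    need = max(need, 1)
    nonzero = (table.abundances > 0).sum(axis=0)
    return table.select_compounds(nonzero >= need)


def rank_sum_test(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Uses exact enumeration when the pooled size is at most 10 with no
    ties, otherwise the normal approximation with mid-ranks, tie
    correction and continuity correction.  Returns ``(p_value, U)`` with U
    counted for the first group.  If every value is identical the test is
    degenerate and p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValidationError("both groups need at least one observation")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0, x.size * y.size / 2.0
    n = pooled.size
    has_ties = np.unique(pooled).size < n
    if n <= 10 and not has_ties:
        res = mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        from scipy.stats import rankdata

        # degenerate tie structure can zero the variance; guard first
        if tiecorrect(rankdata(pooled)) == 0:
            return 1.0, x.size * y.size / 2.0
        res = mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic",
            use_continuity=True,
        )
    return float(min(res.pvalue, 1.0)), float(res.statistic)


@dataclass
class ScreenResult:
    """Per-compound screening outcome with nested kept flags."""

    compound_ids: list[str]
    p_values: np.ndarray
    statistics: np.ndarray
    prevalence: np.ndarray
    alpha: float
    kept_alpha: np.ndarray  # p < alpha
    kept_display: np.ndarray  # p < 0.05

    def kept_ids(self, level: str = "alpha") -> list[str]:
        mask = self.kept_alpha if level == "alpha" else self.kept_display
        return [c for c, k in zip(self.compound_ids, mask) if k]


def screen(table: VocTable, alpha: float = 0.2) -> ScreenResult:
    """Rank-sum screen of every compound between the two cohorts.

    No multiplicity adjustment is applied; raw p-values are compared to
    the liberal model-building cutoff ``alpha`` and to the 0.05 display
    cutoff.
    """
    y = _as_binary(table.labels)
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValidationError("screening needs at least 2 samples per class")
    A = table.abundances
    case, ctrl = A[y == 1], A[y == 0]
    n = A.shape[0]
    if n <= 10:
        p = np.empty(table.n_compounds)
        u = np.empty(table.n_compounds)
        for j in range(table.n_compounds):
            p[j], u[j] = rank_sum_test(case[:, j], ctrl[:, j])
    else:
        # vectorized asymptotic branch of rank_sum_test (mid-ranks, tie and
        # continuity corrections); degenerate all-tied columns get p = 1
        with np.errstate(invalid="ignore", divide="ignore"):
            res = mannwhitneyu(
                case, ctrl, alternative="two-sided", method="asymptotic",
                use_continuity=True, axis=0,
            )
        p = np.asarray(res.pvalue, dtype=float)
        u = np.asarray(res.statistic, dtype=float)
        degenerate = np.all(A == A[0], axis=0)
        p[degenerate | np.isnan(p)] = 1.0
        p = np.minimum(p, 1.0)
    prev = (A > 0).mean(axis=0)
    return ScreenResult(
        compound_ids=list(table.compound_ids),
        p_values=p,
        statistics=u,
        prevalence=prev,
        alpha=alpha,
        kept_alpha=p <= alpha,
        kept_display=p < 0.05,
    )


@dataclass
class RocResult:
    """ROC curve plus the held-out probabilities that produced it."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    jackknife_probs: np.ndarray
    labels: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    n_skipped: int = 0


def roc_from_scores(y: np.ndarray, scores: np.ndarray) -> RocResult:
    """ROC curve and trapezoidal AUC from a fixed score vector.

    The trapezoidal AUC equals the pairwise concordance statistic
    U/(n1*n2) with half-credit for tied scores.
    """
    y = _as_binary(y)
    fpr, tpr, thr = _sk_roc_curve(y, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(
        thresholds=thr, fpr=fpr, tpr=tpr, auc=auc,
        jackknife_probs=np.asarray(scores, dtype=float), labels=y,
    )


def _model_matrix(A: np.ndarray) -> np.ndarray:
    """log1p transform for model fitting; screening stays rank-based."""
    return np.log1p(A)


def fit_final_model(
    table: VocTable,
    prevalence_min: float = 0.03,
    alpha: float = 0.2,
    cv_folds: int = 10,
    seed: int = 0,
    penalty: str = "scad",
    n_lambda: int = 12,
) -> tuple[LogisticFit, ScreenResult]:
    """Run the full selection chain once on the whole table.

    Prevalence filter → rank-sum screen at ``alpha`` → SIS + penalized
    selection → Firth refit on the selected compounds.  Returns the Firth
    fit (intercept-only if nothing survives) and the screen result.
    """
    filtered = prevalence_filter(table, prevalence_min)
    scr = screen(filtered, alpha)
    kept = filtered.select_compounds(scr.kept_alpha)
    y = _as_binary(table.labels)
    if kept.n_compounds == 0:
        fit = firth_fit(np.empty((table.n_samples, 0)), y, feature_names=[])
        return fit, scr
    folds = _usable_folds(y, cv_folds)
    pen = fit_penalized_logistic(
        _model_matrix(kept.abundances), y, folds=folds, seed=seed,
        penalty=penalty, feature_names=kept.compound_ids, n_lambda=n_lambda,
    )
    if not pen.selected_set:
        fit = firth_fit(np.empty((table.n_samples, 0)), y, feature_names=[])
        fit.flags = list(fit.flags) + ["empty_selection"]
        return fit, scr
    cols = [kept.compound_ids.index(c) for c in pen.selected_set]
    X = _model_matrix(kept.abundances[:, cols])
    fit = firth_fit(X, y, feature_names=pen.selected_set)
    fit.tuning_parameter = pen.tuning_parameter
    return fit, scr


def _usable_folds(y: np.ndarray, cv_folds: int) -> int:
    m = int(min((y == 1).sum(), (y == 0).sum()))
    return max(2, min(cv_folds, m))


def jackknife_roc(
    table: VocTable,
    prevalence_min: float = 0.03,
    alpha: float = 0.2,
    cv_folds: int = 10,
    seed: int = 0,
    penalty: str = "scad",
    n_lambda: int = 12,
    firth_in_loop: bool = True,
) -> RocResult:
    """Leave-one-out ROC with selection repeated inside every fold.

    For each held-out sample the prevalence filter, rank-sum screen,
    penalized selection, and (by default) the Firth refit are all redone
    on the remaining samples; the held-out predicted probabilities are
    assembled into the ROC.  This is what controls the over-optimism that
    in-sample selection would otherwise induce.  ``firth_in_loop=False``
    uses the penalized fit itself for held-out prediction.
    """
    y_all = _as_binary(table.labels)
    if (y_all == 1).sum() < 3 or (y_all == 0).sum() < 3:
        raise ValidationError("jackknife needs at least 3 samples per class")
    n = table.n_samples
    probs = np.full(n, np.nan)
    skipped = 0
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        sub = table.select_samples(keep)
        y = _as_binary(sub.labels)
        if len(np.unique(y)) < 2:
            warnings.warn(f"fold {i}: a class is absent; skipped")
            skipped += 1
            continue
        filtered = prevalence_filter(sub, prevalence_min)
        scr = screen(filtered, alpha)
        kept = filtered.select_compounds(scr.kept_alpha)
        if kept.n_compounds == 0:
            # constant scores carry no ranking information; 0.5 avoids the
            # leave-one-out prior artifact (training mean shifts against the
            # held-out label by 1/(n-1))
            probs[i] = 0.5
            continue
        folds = _usable_folds(y, cv_folds)
        pen = fit_penalized_logistic(
            _model_matrix(kept.abundances), y, folds=folds, seed=seed,
            penalty=penalty, feature_names=kept.compound_ids,
            n_lambda=n_lambda,
        )
        cols_all = [table.compound_ids.index(c) for c in pen.selected_set]
        if not pen.selected_set:
            probs[i] = 0.5
            continue
        x_held = _model_matrix(table.abundances[i, cols_all])
        if firth_in_loop:
            cols = [kept.compound_ids.index(c) for c in pen.selected_set]
            fit = firth_fit(
                _model_matrix(kept.abundances[:, cols]), y,
                feature_names=pen.selected_set,
            )
            probs[i] = float(fit.predict_proba(x_held)[0])
        else:
            sel = [pen.feature_names.index(c) for c in pen.selected_set]
            eta = pen.intercept + float(np.asarray(x_held) @ pen.coefficients[sel])
            probs[i] = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))

    ok = ~np.isnan(probs)
    res = roc_from_scores(y_all[ok], probs[ok])
    res.jackknife_probs = probs
    res.labels = y_all
    res.sample_ids = list(table.sample_ids)
    res.n_skipped = skipped
    return res
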
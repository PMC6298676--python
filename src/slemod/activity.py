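"""Disease-activity prediction from module enrichment scores.

Single-sample enrichment scores of co-expression modules (one column per
cell-type module) feed a logistic regression with an elastic-net penalty;
the penalty strength is chosen by stratified cross-validated deviance with
the one-standard-error rule.  Model quality is summarized by ROC/AUC, and
per-module association with active disease by the odds ratio

    OR = (enriched_active * nonenriched_inactive)
         / (nonenriched_active * enriched_inactive)

over binary expected-versus-observed enrichment calls, with the
Haldane-Anscombe 0.5 correction when any cell is zero and a log-normal
95% confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

from .data import ExpressionSet, GeneSetCollection
from .enrich import EnrichmentMatrix, gene_level_stats, score_gene_sets

__all__ = [
    "ActivityClassifier",
    "ROCResult",
    "build_features",
    "fit_activity_glm",
    "roc_auc",
    "call_enrichment",
    "odds_ratio_active",
    "cross_validated_scores",
]


def build_features(
    merged: ExpressionSet,
    modules_by_celltype: GeneSetCollection,
    tau: float = 1.0,
    mode: str = "diff",
) -> EnrichmentMatrix:
    """Single-sample enrichment features (samples x module gene sets).

    Each module list is scored against the merged expression set; modules
    with no overlapping genes are dropped with a warning (their columns are
    missing in the result).
    """
    z = gene_level_stats(merged)
    em = score_gene_sets(z, modules_by_celltype, tau=tau, mode=mode)
    keep = [c for c in em.scores.columns if em.overlap.get(c, 0) > 0]
    em.scores = em.scores[keep]
    return em


class ActivityClassifier(BaseEstimator, ClassifierMixin):
    """Elastic-net logistic regression with CV-selected penalty strength.

    Parameters
    ----------
    alpha : float
        Elastic-net mixing parameter in [0, 1] (1 = lasso, 0 = ridge).
    n_folds : int
        Stratified CV folds for the penalty path.
    n_lambdas : int
        Length of the geometric penalty path from lambda_max down to
        ``lambda_min_ratio * lambda_max``.
    lambda_min_ratio : float
    one_se : bool
        Apply the one-standard-error rule (largest penalty within one SE of
        the minimum cross-validated deviance); otherwise take the minimum.
    random_state : int or None
        Seeds the CV fold shuffling; fitting is deterministic given it.

    Fitted attributes: ``coef_``, ``intercept_`` (on the original feature
    scale), ``lambda_``, ``lambda_path_``, ``cv_deviance_``, ``classes_``.
    """

    def __init__(
        self,
        alpha: float = 0.5,
        n_folds: int = 5,
        n_lambdas: int = 30,
        lambda_min_ratio: float = 1e-3,
        one_se: bool = True,
        random_state=None,
    ):
        self.alpha = alpha
        self.n_folds = n_folds
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.one_se = one_se
        self.random_state = random_state

    # internal: sklearn's C for a glmnet-style per-observation penalty lambda
    @staticmethod
    def _solver(alpha: float, lam: float, n: int) -> LogisticRegression:
        return LogisticRegression(
            solver="saga",
            l1_ratio=alpha,
            C=1.0 / max(n * lam, 1e-12),
            max_iter=20000,
            tol=1e-7,
            random_state=0,  # saga shuffles samples internally; pin it
        )

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must be in [0, 1]")
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError(f"need exactly two classes, got {classes.tolist()}")
        n = X.shape[0]
        if n < 2 * self.n_folds:
            raise ValueError("need at least 2 samples per CV fold")
        self.classes_ = classes
        y01 = (y == classes[1]).astype(float)

        self._scaler = StandardScaler().fit(X)
        Xs = self._scaler.transform(X)

        lam_max = np.abs(Xs.T @ (y01 - y01.mean())).max() / (n * max(self.alpha, 1e-3))
        lam_max = max(lam_max, 1e-6)
        path = np.geomspace(lam_max, lam_max * self.lambda_min_ratio, self.n_lambdas)

        skf = StratifiedKFold(
            n_splits=self.n_folds, shuffle=True, random_state=self.random_state
        )
        folds = list(skf.split(Xs, y01))
        dev = np.zeros((self.n_lambdas, self.n_folds))
        for j, lam in enumerate(path):
            for f, (tr, te) in enumerate(folds):
                model = self._solver(self.alpha, lam, len(tr)).fit(Xs[tr], y01[tr])
                p = np.clip(model.predict_proba(Xs[te])[:, 1], 1e-12, 1 - 1e-12)
                dev[j, f] = -2.0 * np.mean(
                    y01[te] * np.log(p) + (1 - y01[te]) * np.log(1 - p)
                )
        mean_dev = dev.mean(axis=1)
        se_dev = dev.std(axis=1, ddof=1) / np.sqrt(self.n_folds)
        j_min = int(np.argmin(mean_dev))
        if self.one_se:
            threshold = mean_dev[j_min] + se_dev[j_min]
            j_best = int(np.flatnonzero(mean_dev <= threshold)[0])  # largest lambda
        else:
            j_best = j_min
        self.lambda_path_ = path
        self.cv_deviance_ = mean_dev
        self.cv_deviance_se_ = se_dev
        self.lambda_ = float(path[j_best])

        final = self._solver(self.alpha, self.lambda_, n).fit(Xs, y01)
        scale = self._scaler.scale_
        self.coef_ = (final.coef_ / scale).reshape(1, -1)
        self.intercept_ = final.intercept_ - (final.coef_ / scale) @ self._scaler.mean_
        self._final = final
        return self

    def decision_function(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        return X @ self.coef_.ravel() + self.intercept_.ravel()[0]

    def predict_proba(self, X):
        d = self.decision_function(X)
        p = 1.0 / (1.0 + np.exp(-d))
        return np.column_stack([1 - p, p])

    def predict(self, X):
        return self.classes_[(self.decision_function(X) > 0).astype(int)]


def fit_activity_glm(
    features: EnrichmentMatrix | pd.DataFrame,
    labels,
    alpha: float = 0.5,
    n_folds: int = 5,
    seed=None,
) -> ActivityClassifier:
    """Fit the penalized activity GLM on an enrichment-score feature matrix."""
    X = features.scores if isinstance(features, EnrichmentMatrix) else features
    model = ActivityClassifier(alpha=alpha, n_folds=n_folds, random_state=seed)
    model.fit(np.asarray(X, dtype=float), np.asarray(labels))
    model.feature_names_ = list(X.columns) if hasattr(X, "columns") else None
    return model


@dataclass
class ROCResult:
    """ROC curve and area under it."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_auc(model_or_scores, features=None, labels=None) -> ROCResult:
    """ROC curve and trapezoid AUC.

    Either ``roc_auc(model, features, labels)`` with a fitted classifier, or
    ``roc_auc(scores, labels=...)`` with raw scores.  The positive class is
    ``model.classes_[1]`` (or label 1).
    """
    if features is not None:
        X = features.scores if isinstance(features, EnrichmentMatrix) else features
        scores = model_or_scores.predict_proba(np.asarray(X, dtype=float))[:, 1]
        y = np.asarray(labels) == model_or_scores.classes_[1]
    else:
        scores = np.asarray(model_or_scores, dtype=float)
        y = np.asarray(labels).astype(bool)
    if y.all() or not y.any():
        raise ValueError("evaluation set must contain both classes")
    fpr, tpr, thresholds = roc_curve(y, scores)
    return ROCResult(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=float(_trapezoid_auc(fpr, tpr)))


def cross_validated_scores(
    features: EnrichmentMatrix | pd.DataFrame,
    labels,
    alpha: float = 0.5,
    n_folds: int = 5,
    seed=None,
) -> np.ndarray:
    """Held-out predicted probabilities from an outer stratified K-fold loop.

    Each fold's model (including its inner penalty-path CV) is fit on the
    training split only; returned scores are out-of-fold probabilities for
    the positive class, aligned with the input rows.
    """
    X = np.asarray(
        features.scores if isinstance(features, EnrichmentMatrix) else features,
        dtype=float,
    )
    y = np.asarray(labels)
    base = ActivityClassifier(alpha=alpha, n_folds=n_folds, random_state=seed)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    out = np.full(len(y), np.nan)
    for tr, te in skf.split(X, y):
        model = clone(base).fit(X[tr], y[tr])
        out[te] = model.predict_proba(X[te])[:, 1]
    return out


def call_enrichment(
    scores: EnrichmentMatrix | pd.DataFrame,
    directions: dict[str, int],
    threshold: float = 0.0,
) -> pd.DataFrame:
    """Binary expected-versus-observed enrichment calls.

    A sample is called enriched for a module when ``direction * score``
    exceeds ``threshold``, where ``direction`` is the module's expected
    sign of association with disease activity (+1 or -1).  Every scored
    module needs a direction.
    """
    frame = scores.scores if isinstance(scores, EnrichmentMatrix) else scores
    missing = [c for c in frame.columns if c not in directions]
    if missing:
        raise KeyError(f"no expected direction for modules: {missing}")
    bad = [c for c in frame.columns if directions[c] not in (-1, 1)]
    if bad:
        raise ValueError(f"directions must be +1 or -1; offending modules: {bad}")
    calls = {}
    for col in frame.columns:
        calls[col] = directions[col] * frame[col] > threshold
    return pd.DataFrame(calls, index=frame.index)


@dataclass
class ORTable:
    """Per-module odds ratios for active disease."""

    table: pd.DataFrame
    threshold: float = 0.0


def odds_ratio_active(
    enriched: pd.DataFrame, labels, threshold: float = 0.0
) -> ORTable:
    """Odds ratio of active disease given module enrichment.

    ``enriched`` is a samples x modules boolean matrix; ``labels`` marks
    active samples (truthy = active, falsy = inactive).  The OR is
    (enriched_active * nonenriched_inactive) /
    (nonenriched_active * enriched_inactive); when any cell is zero, 0.5 is
    added to every cell (Haldane-Anscombe) and the row is flagged.  The 95%
    CI uses the log-OR normal approximation.
    """
    active = np.asarray(labels).astype(bool)
    rows = []
    for module in enriched.columns:
        e = enriched[module].to_numpy().astype(bool)
        ea = int((e & active).sum())
        na = int((~e & active).sum())
        ei = int((e & ~active).sum())
        ni = int((~e & ~active).sum())
        cells = np.array([ea, na, ei, ni], dtype=float)
        corrected = bool((cells == 0).any())
        if corrected:
            cells = cells + 0.5
        ea_c, na_c, ei_c, ni_c = cells
        odds = (ea_c * ni_c) / (na_c * ei_c)
        se = np.sqrt((1.0 / cells).sum())
        ci = (float(odds * np.exp(-1.96 * se)), float(odds * np.exp(1.96 * se)))
        rows.append(
            {
                "module": module,
                "enriched_active": ea,
                "nonenriched_active": na,
                "enriched_inactive": ei,
                "nonenriched_inactive": ni,
                "or": float(odds),
                "ci_low": ci[0],
                "ci_high": ci[1],
                "haldane_corrected": corrected,
            }
        )
    return ORTable(table=pd.DataFrame(rows).set_index("module"), threshold=threshold)
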
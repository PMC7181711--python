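"""Classification and evaluation models for treatment response.

The feature tables feed three families of linear classifiers, all with the
treated responder as the positive class:

* PCA-LDA: z-scored features reduced by PCA (top 16 components for
  PCA-LDA1, top 2 for PCA-LDA2) followed by Fisher linear discriminant
  analysis;
* ROI-LDA / single-parameter LDA: the same discriminant on the ROI-averaged
  conventional bolus parameters (PE, AUC, TP, MTT), combined or singly;
* an elastic-net-penalized logistic regression (glmnet-style) over a
  log-spaced lambda path with the lambda minimizing 10-fold CV deviance.

Evaluation pools out-of-fold decision scores from stratified 10-fold CV
into one ROC; the AUC confidence interval uses the DeLong variance.  The
whole preprocessing chain (median imputation, standardization, PCA) is
refit inside every training fold, so no information leaks from held-out
rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.exceptions import ConvergenceWarning
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.impute import SimpleImputer
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.power import TTestIndPower

__all__ = [
    "DeterministicPCA",
    "PCALDAClassifier",
    "ROILDAClassifier",
    "ElasticNetLogisticCV",
    "ROCResult",
    "roc_with_ci",
    "cv_evaluate",
    "spearman_to_mvd",
    "two_sample_power",
]


class DeterministicPCA(PCA):
    """PCA with a fixed sign convention.

    After fitting, every component is flipped so that its largest-magnitude
    loading is positive, making scores reproducible across platforms and
    BLAS builds.  Full SVD solver for determinism.
    """

    def __init__(self, n_components=None):
        super().__init__(n_components=n_components, svd_solver="full")

    def fit(self, X, y=None):
        super().fit(X, y)
        flip = np.sign(self.components_[
            np.arange(self.components_.shape[0]),
            np.argmax(np.abs(self.components_), axis=1),
        ])
        flip[flip == 0] = 1.0
        self.components_ *= flip[:, None]
        return self


class _PipelineClassifier(BaseEstimator, ClassifierMixin):
    """Shared scaffolding: impute-by-median, z-score, then a linear model."""

    def _steps(self):  # pragma: no cover - abstract
        raise NotImplementedError

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError("need exactly two classes")
        if X.shape[0] < 2:
            raise ValueError("need at least 2 rows")
        self.classes_ = classes
        self.pipeline_ = Pipeline(self._steps())
        self.pipeline_.fit(X, y)
        return self

    def decision_function(self, X):
        check_is_fitted(self, "pipeline_")
        return self.pipeline_.decision_function(np.asarray(X, dtype=float))

    def predict(self, X):
        scores = self.decision_function(X)
        return np.where(scores > 0, self.classes_[1], self.classes_[0])

    def predict_proba(self, X):
        check_is_fitted(self, "pipeline_")
        return self.pipeline_.predict_proba(np.asarray(X, dtype=float))


class PCALDAClassifier(_PipelineClassifier):
    """LDA on the top principal-component scores of z-scored features.

    ``n_components=16`` gives PCA-LDA1, ``n_components=2`` PCA-LDA2.  The
    requested component count is capped at the feasible rank of the
    training block.
    """

    def __init__(self, n_components: int = 2, lda_shrinkage=None):
        self.n_components = n_components
        self.lda_shrinkage = lda_shrinkage

    def _steps(self):
        solver = "lsqr" if self.lda_shrinkage is not None else "svd"
        return [
            ("impute", SimpleImputer(strategy="median", keep_empty_features=True)),
            ("scale", StandardScaler()),
            ("pca", DeterministicPCA(n_components=self._n_eff)),
            ("lda", LinearDiscriminantAnalysis(solver=solver,
                                               shrinkage=self.lda_shrinkage)),
        ]

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        self._n_eff = int(min(self.n_components, X.shape[0] - 1, X.shape[1]))
        if self._n_eff < 1:
            raise ValueError("not enough rows/columns for PCA")
        return super().fit(X, y)

    @property
    def explained_variance_ratio_(self):
        check_is_fitted(self, "pipeline_")
        return self.pipeline_.named_steps["pca"].explained_variance_ratio_


class ROILDAClassifier(_PipelineClassifier):
    """LDA on conventional ROI parameters (or any small feature block)."""

    def __init__(self, ridge: float = 1e-6):
        self.ridge = ridge

    def _steps(self):
        return [
            ("impute", SimpleImputer(strategy="median", keep_empty_features=True)),
            ("scale", StandardScaler()),
            ("lda", LinearDiscriminantAnalysis(solver="svd")),
        ]


class ElasticNetLogisticCV(BaseEstimator, ClassifierMixin):
    """glmnet-style elastic-net logistic regression with CV lambda choice.

    The penalty is lambda * (alpha * ||b||_1 + (1-alpha)/2 * ||b||_2^2) on
    standardized features.  A log-spaced path of ``n_lambda`` values runs
    from lambda_max (the smallest lambda with an all-zero solution, from
    the KKT condition max |X^T (y - ybar)| / (n alpha)) down by the factor
    ``lambda_min_ratio``; lambda is chosen to minimize the mean out-of-fold
    binomial deviance over ``cv`` stratified folds.  Coefficients are
    reported on the original feature scale.
    """

    def __init__(self, alpha: float = 0.5, n_lambda: int = 30,
                 lambda_min_ratio: float = 0.01, cv: int = 10,
                 random_state: int = 0, max_iter: int = 500):
        self.alpha = alpha
        self.n_lambda = n_lambda
        self.lambda_min_ratio = lambda_min_ratio
        self.cv = cv
        self.random_state = random_state
        self.max_iter = max_iter

    def _path(self, Xs, y01):
        n = Xs.shape[0]
        resid = y01 - y01.mean()
        lam_max = np.max(np.abs(Xs.T @ resid)) / (n * max(self.alpha, 1e-3))
        lam_max = max(lam_max, 1e-6)
        return np.geomspace(lam_max, lam_max * self.lambda_min_ratio,
                            self.n_lambda)

    def _fit_one(self, Xs, y01, lam):
        # sklearn minimizes  sum(loss) + (1/C) * penalty ; glmnet minimizes
        # (1/n) sum(loss) + lam * penalty  =>  C = 1 / (n * lam)
        n = Xs.shape[0]
        clf = LogisticRegression(
            solver="saga", l1_ratio=self.alpha,
            C=1.0 / (n * lam), max_iter=self.max_iter, tol=1e-5,
            random_state=0,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            clf.fit(Xs, y01)
        return clf

    def _fit_path(self, Xs, y01, lambdas):
        """Warm-started saga fits down the decreasing lambda path.

        Yields (lam, coef, intercept); warm starts make the whole path cost
        little more than the hardest single fit (the glmnet pathwise
        strategy).
        """
        n = Xs.shape[0]
        clf = LogisticRegression(
            solver="saga", l1_ratio=self.alpha, warm_start=True,
            max_iter=self.max_iter, tol=1e-5, random_state=0,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            for lam in lambdas:
                clf.C = 1.0 / (n * lam)
                clf.fit(Xs, y01)
                yield lam, clf.coef_.ravel().copy(), float(clf.intercept_[0])

    def fit(self, X, y):
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError("need exactly two classes")
        self.classes_ = classes
        y01 = (y == classes[1]).astype(float)

        self.imputer_ = SimpleImputer(strategy="median", keep_empty_features=True).fit(X)
        Xi = self.imputer_.transform(X)
        self.scaler_ = StandardScaler().fit(Xi)
        Xs = self.scaler_.transform(Xi)

        lambdas = self._path(Xs, y01)
        k = int(min(self.cv, np.bincount(y01.astype(int)).min()))
        k = max(k, 2)
        skf = StratifiedKFold(n_splits=k, shuffle=True,
                              random_state=self.random_state)
        folds = list(skf.split(Xs, y01))
        deviance = np.zeros(len(lambdas))
        eps = 1e-12
        for tr, te in folds:
            for j, (_, coef, b0) in enumerate(
                    self._fit_path(Xs[tr], y01[tr], lambdas)):
                s = Xs[te] @ coef + b0
                p = np.clip(1.0 / (1.0 + np.exp(-s)), eps, 1 - eps)
                deviance[j] += -2.0 * np.sum(
                    y01[te] * np.log(p) + (1 - y01[te]) * np.log(1 - p))
        self.cv_deviance_ = deviance / len(y01)
        self.lambda_path_ = lambdas
        best = int(np.argmin(deviance))
        self.lambda_ = float(lambdas[best])
        self.cv_folds_ = folds

        # refit on all data down the path to the selected lambda (warm start)
        for lam, coef, b0 in self._fit_path(Xs, y01, lambdas[:best + 1]):
            pass
        scale = self.scaler_.scale_
        self.coef_std_ = coef
        self.coef_ = self.coef_std_ / scale
        self.intercept_ = float(b0 - np.sum(self.coef_ * self.scaler_.mean_))
        self.selected_features_ = np.flatnonzero(np.abs(self.coef_std_) > 1e-10)
        return self

    def decision_function(self, X):
        check_is_fitted(self, "coef_")
        X = self.imputer_.transform(np.asarray(X, dtype=float))
        return X @ self.coef_ + self.intercept_

    def predict_proba(self, X):
        s = self.decision_function(X)
        p = 1.0 / (1.0 + np.exp(-s))
        return np.column_stack([1 - p, p])

    def predict(self, X):
        return np.where(self.decision_function(X) > 0,
                        self.classes_[1], self.classes_[0])


# ---------------------------------------------------------------------------
# ROC with DeLong confidence interval
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ROCResult:
    auc: float
    ci_low: float
    ci_high: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


def _midrank(x):
    return sps.rankdata(x, method="average")


def roc_with_ci(scores, labels, ci_level: float = 0.95) -> ROCResult:
    """Empirical ROC; AUC as the Mann–Whitney statistic with midranks for
    ties; CI from the DeLong (placement-value) variance estimator."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos, neg = scores[labels], scores[~labels]
    m, n = pos.size, neg.size
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    all_r = _midrank(np.concatenate([pos, neg]))
    r_pos, r_neg = all_r[:m], all_r[m:]
    auc = (r_pos.sum() - m * (m + 1) / 2.0) / (m * n)
    # placements
    v_pos = (r_pos - _midrank(pos)) / n          # P(score_neg < pos_i) w/ ties
    v_neg = 1.0 - (r_neg - _midrank(neg)) / m
    s_pos = v_pos.var(ddof=1) if m > 1 else 0.0
    s_neg = v_neg.var(ddof=1) if n > 1 else 0.0
    se = np.sqrt(s_pos / m + s_neg / n)
    z = sps.norm.ppf(0.5 + ci_level / 2.0)
    lo, hi = max(0.0, auc - z * se), min(1.0, auc + z * se)
    fpr, tpr, thr = roc_curve(labels.astype(int), scores)
    return ROCResult(float(auc), float(lo), float(hi), fpr, tpr, thr)


def cv_evaluate(estimator, X, y, k: int = 10, seed: int = 0) -> ROCResult:
    """Stratified k-fold CV; pools out-of-fold decision scores into one ROC.

    The estimator (including its internal imputation/standardization/PCA)
    is cloned and refit on every training fold, so held-out rows never
    influence preprocessing.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("need exactly two classes")
    y01 = (y == classes[1]).astype(int)
    min_class = np.bincount(y01).min()
    k_eff = int(min(k, min_class))
    if k_eff < 2:
        raise ValueError("class too small for cross-validation")
    skf = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=seed)
    oof = np.empty(len(y), dtype=float)
    for tr, te in skf.split(X, y01):
        model = clone(estimator).fit(X[tr], y[tr])
        oof[te] = model.decision_function(X[te])
    return roc_with_ci(oof, y01.astype(bool))


# ---------------------------------------------------------------------------
# correlation to histology and power
# ---------------------------------------------------------------------------

def spearman_to_mvd(values, mvd, exact_max_n: int = 9):
    """Midrank Spearman correlation of a biomarker with microvessel density.

    Exact permutation p-value for n <= ``exact_max_n``; the usual
    t-approximation otherwise.  Constant input yields (nan, nan).
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(mvd, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 5:
        raise ValueError("need at least 5 paired finite values")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return np.nan, np.nan
    rho = float(sps.spearmanr(x, y).statistic)
    n = x.size
    if n <= exact_max_n:
        # under permutation the rank multisets are fixed, so |rho| is a
        # monotone function of |sum(rx * ry_perm) - n * mean(rx) * mean(ry)|
        from itertools import permutations

        rx, ry = _midrank(x), _midrank(y)
        center = n * rx.mean() * ry.mean()
        perms = np.array(list(permutations(range(n))), dtype=np.int64)
        stats = np.abs(ry[perms] @ rx - center)
        obs = abs(float(rx @ ry) - center)
        return rho, float(np.mean(stats >= obs - 1e-9))
    p = float(sps.spearmanr(x, y).pvalue)
    return rho, p


def two_sample_power(n_per_group: int, effect_sd: float, alpha_2sided: float = 0.05,
                     method: str = "t", n_sim: int = 10_000, seed: int = 0) -> float:
    """Power of a two-sided two-sample location test.

    ``method='t'`` is the exact noncentral-t power of the pooled t-test;
    ``'normal'`` the large-sample normal approximation; ``'simulate'``
    draws Normal(0,1) vs Normal(effect_sd,1) samples and reports the t-test
    rejection fraction over ``n_sim`` replicates (vectorized).
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if effect_sd < 0:
        raise ValueError("effect_sd must be >= 0")
    if method == "t":
        if effect_sd == 0:
            return alpha_2sided
        return float(TTestIndPower().power(effect_size=effect_sd,
                                           nobs1=n_per_group,
                                           alpha=alpha_2sided))
    if method == "normal":
        z = sps.norm.ppf(1 - alpha_2sided / 2)
        d = effect_sd * np.sqrt(n_per_group / 2.0)
        return float(sps.norm.cdf(d - z) + sps.norm.cdf(-d - z))
    if method == "simulate":
        rng = np.random.default_rng(seed)
        a = rng.standard_normal((n_sim, n_per_group))
        b = rng.standard_normal((n_sim, n_per_group)) + effect_sd
        p = sps.ttest_ind(a, b, axis=1).pvalue
        return float(np.mean(p < alpha_2sided))
    raise ValueError("method must be 't', 'normal' or 'simulate'")
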
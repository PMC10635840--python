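"""Statistical core: correlation PCA with Kaiser retention, t-test +
bootstrap component selection, Fisher linear discriminant with LOOCV,
ROC/AUC with DeLong or bootstrap CI, diagnostic metrics, and the
confounder regression of component scores on clinical covariates.

Conventions
-----------
* PCA standardizes each feature to zero mean / unit variance using the
  training subjects only (correlation PCA); components with eigenvalue
  > 1 are retained (Kaiser), with a floor of one component.  Loading
  signs are fixed by making the largest-magnitude element positive.
* The two-sample comparison is Student's pooled-variance t-test
  (two-sided), with a Welch fallback when a group has zero variance.
* The discriminant is the two-class Fisher rule with equal priors:
  ``w = S_pooled^{-1} (mu1 - mu0)`` and the boundary at the midpoint of
  the projected class means; class 1 is predicted above the boundary.
* AUC is the Mann-Whitney concordance probability (ties count 1/2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_curve

__all__ = [
    "PCModel", "TTestResult", "DiscriminantModel", "ROCResult",
    "MetricsReport", "RegressionResult",
    "fit_pca", "project_pca", "select_components", "bootstrap_validate",
    "fit_lda", "loocv", "compute_roc", "compute_metrics",
    "confounder_regression",
]


# --------------------------------------------------------------------------
# PCA

@dataclass
class PCModel:
    """Correlation-PCA model fit on training subjects only."""

    mean_: np.ndarray
    scale_: np.ndarray
    loadings: np.ndarray          # (p, p) columns = components, descending
    eigenvalues: np.ndarray
    retained: int
    feature_names: tuple[str, ...] | None = None
    fit_subject_ids: tuple[str, ...] | None = None
    dropped_features: tuple[int, ...] = ()

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        return self.eigenvalues / self.eigenvalues.sum()


def _as_matrix(X) -> tuple[np.ndarray, tuple[str, ...] | None]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), tuple(map(str, X.columns))
    return np.asarray(X, dtype=float), None


def _colmat(a) -> np.ndarray:
    """Coerce scores to (n_subjects, k): a 1-D vector is one column."""
    a = np.asarray(a, dtype=float)
    return a[:, None] if a.ndim == 1 else a


def fit_pca(X, feature_names=None, subject_ids=None) -> PCModel:
    """Fit correlation PCA with Kaiser retention (eigenvalue > 1, min 1).

    Zero-variance features are dropped with a warning; fewer than two
    subjects or features is an error, as are missing values.
    """
    M, names = _as_matrix(X)
    if feature_names is not None:
        names = tuple(feature_names)
    n, p = M.shape if M.ndim == 2 else (0, 0)
    if n < 2 or p < 2:
        raise ValueError("need at least 2 subjects and 2 features")
    if not np.all(np.isfinite(M)):
        raise ValueError("feature matrix contains missing/nonfinite values")
    sd = M.std(axis=0, ddof=1)
    dropped = tuple(int(i) for i in np.flatnonzero(sd == 0))
    if dropped:
        warnings.warn(f"dropping zero-variance feature columns {dropped}")
        keep = np.flatnonzero(sd > 0)
        M = M[:, keep]
        sd = sd[keep]
        if names is not None:
            names = tuple(names[i] for i in keep)
        if M.shape[1] < 2:
            raise ValueError("fewer than 2 non-constant features")
    mean = M.mean(axis=0)
    Z = (M - mean) / sd
    C = (Z.T @ Z) / (n - 1)
    eigval, eigvec = np.linalg.eigh(C)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # deterministic sign: largest-magnitude loading element positive
    for j in range(eigvec.shape[1]):
        k = int(np.argmax(np.abs(eigvec[:, j])))
        if eigvec[k, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    retained = max(1, int(np.sum(eigval > 1.0)))
    return PCModel(mean_=mean, scale_=sd, loadings=eigvec,
                   eigenvalues=eigval, retained=retained,
                   feature_names=names,
                   fit_subject_ids=tuple(subject_ids) if subject_ids is not None else None,
                   dropped_features=dropped)


def project_pca(model: PCModel, X, n_components: int | None = None) -> np.ndarray:
    """Project (possibly held-out) subjects onto the retained components.

    Standardization uses the training mean/SD, so the projection applies
    unchanged to validation subjects.
    """
    M, _ = _as_matrix(X)
    M = np.atleast_2d(M)
    if model.dropped_features:
        keep = [i for i in range(M.shape[1]) if i not in model.dropped_features]
        M = M[:, keep]
    if M.shape[1] != model.mean_.size:
        raise ValueError(
            f"feature dimension {M.shape[1]} does not match model "
            f"({model.mean_.size})")
    k = model.retained if n_components is None else n_components
    Z = (M - model.mean_) / model.scale_
    return Z @ model.loadings[:, :k]


# --------------------------------------------------------------------------
# Component selection

@dataclass
class TTestResult:
    """Two-sample t-test for one principal component."""

    component: int          # 1-based PC index
    t: float
    p: float
    selected: bool
    bootstrap_support: float | None = None
    flags: tuple[str, ...] = ()


def _pooled_t(x0: np.ndarray, x1: np.ndarray) -> tuple[float, float, tuple[str, ...]]:
    n0, n1 = x0.size, x1.size
    v0, v1 = x0.var(ddof=1), x1.var(ddof=1)
    if v0 == 0 and v1 == 0:
        if x0.mean() == x1.mean():
            return 0.0, 1.0, ("degenerate_zero_variance",)
        return np.inf, 0.0, ("degenerate_zero_variance",)
    if v0 == 0 or v1 == 0:
        t, p = sps.ttest_ind(x0, x1, equal_var=False)
        return float(t), float(p), ("welch_fallback",)
    sp2 = ((n0 - 1) * v0 + (n1 - 1) * v1) / (n0 + n1 - 2)
    t = (x1.mean() - x0.mean()) / np.sqrt(sp2 * (1 / n0 + 1 / n1))
    p = 2.0 * sps.t.sf(abs(t), n0 + n1 - 2)
    return float(t), float(p), ()


def select_components(scores: np.ndarray, labels: np.ndarray,
                      alpha: float = 0.05) -> list[TTestResult]:
    """Student t-test per component; selected when two-sided p < alpha."""
    scores = _colmat(scores)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("exactly two groups required")
    m0, m1 = y == classes[0], y == classes[1]
    if m0.sum() < 2 or m1.sum() < 2:
        raise ValueError("each group needs n >= 2")
    out = []
    for j in range(scores.shape[1]):
        t, p, flags = _pooled_t(scores[m0, j], scores[m1, j])
        out.append(TTestResult(component=j + 1, t=t, p=p,
                               selected=bool(p < alpha), flags=flags))
    return out


def bootstrap_validate(scores: np.ndarray, labels: np.ndarray,
                       n_boot: int = 1000, alpha: float = 0.05,
                       seed: int = 0) -> np.ndarray:
    """Fraction of bootstrap resamples in which each component's t-test
    stays significant (p < alpha).

    Subjects are resampled with replacement within each group; the same
    resample is used for every component.  Degenerate resamples (zero
    pooled variance) are redrawn.
    """
    scores = _colmat(scores)
    y = np.asarray(labels)
    classes = np.unique(y)
    x0, x1 = scores[y == classes[0]], scores[y == classes[1]]
    n0, n1 = x0.shape[0], x1.shape[0]
    if n0 < 2 or n1 < 2:
        raise ValueError("each group needs n >= 2")
    rng = np.random.default_rng(seed)

    def batch(b):
        i0 = rng.integers(0, n0, (b, n0))
        i1 = rng.integers(0, n1, (b, n1))
        s0, s1 = x0[i0], x1[i1]            # (b, n, k)
        m0, m1 = s0.mean(axis=1), s1.mean(axis=1)
        v0, v1 = s0.var(axis=1, ddof=1), s1.var(axis=1, ddof=1)
        sp2 = ((n0 - 1) * v0 + (n1 - 1) * v1) / (n0 + n1 - 2)
        ok = np.all(sp2 > 0, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (m1 - m0) / np.sqrt(sp2 * (1 / n0 + 1 / n1))
        p = 2.0 * sps.t.sf(np.abs(t), n0 + n1 - 2)
        return p[ok]

    ps = batch(n_boot)
    guard = 0
    while ps.shape[0] < n_boot and guard < 100:
        ps = np.vstack([ps, batch(n_boot - ps.shape[0])])
        guard += 1
    return (ps[:n_boot] < alpha).mean(axis=0)


# --------------------------------------------------------------------------
# Linear discriminant

@dataclass
class DiscriminantModel:
    """Two-class Fisher discriminant with midpoint threshold."""

    weights: np.ndarray
    threshold: float
    class_means: np.ndarray       # (2, k), rows ordered as `classes`
    pooled_cov: np.ndarray
    classes: tuple
    ridge: float = 0.0

    def decision(self, X) -> np.ndarray:
        """Signed discriminant score; > 0 predicts ``classes[1]``."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None] if self.weights.size == 1 else X[None, :]
        return X @ self.weights - self.threshold

    def predict(self, X) -> np.ndarray:
        d = self.decision(X)
        return np.where(d > 0, self.classes[1], self.classes[0])


def fit_lda(scores: np.ndarray, labels: np.ndarray,
            ridge: float | None = None) -> DiscriminantModel:
    """Fit the two-class Fisher discriminant (equal priors).

    A singular pooled covariance gets a small ridge (logged on the
    model) unless an explicit ridge is supplied.
    """
    X = _colmat(scores)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("exactly two classes required")
    X0, X1 = X[y == classes[0]], X[y == classes[1]]
    if len(X0) < 2 or len(X1) < 2:
        raise ValueError("each class needs n >= 2")
    mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
    n0, n1 = len(X0), len(X1)
    S = ((X0 - mu0).T @ (X0 - mu0) + (X1 - mu1).T @ (X1 - mu1)) / (n0 + n1 - 2)
    used_ridge = 0.0
    if ridge:
        S = S + ridge * np.eye(S.shape[0])
        used_ridge = ridge
    try:
        w = np.linalg.solve(S, mu1 - mu0)
        if not np.all(np.isfinite(w)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        used_ridge = 1e-8 * max(np.trace(S) / S.shape[0], 1.0)
        w = np.linalg.solve(S + used_ridge * np.eye(S.shape[0]), mu1 - mu0)
    threshold = float(w @ (mu0 + mu1) / 2.0)
    return DiscriminantModel(weights=w, threshold=threshold,
                             class_means=np.vstack([mu0, mu1]),
                             pooled_cov=S, classes=tuple(classes),
                             ridge=used_ridge)


def loocv(scores: np.ndarray, labels: np.ndarray,
          ridge: float | None = None):
    """Leave-one-out cross-validation of the discriminant.

    Refits the discriminant on the remaining n-1 subjects for every
    held-out subject.  Returns ``(cv_accuracy_pct, heldout_scores,
    predictions)`` where held-out scores are signed decision values
    (0 = per-fold boundary), usable for an ROC over all thresholds.
    """
    X = _colmat(scores)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("exactly two classes required")
    for c in classes:
        if (y == c).sum() < 3:
            raise ValueError("each class needs n >= 3 for LOOCV")
    n = X.shape[0]
    heldout = np.empty(n)
    preds = np.empty(n, dtype=y.dtype)
    idx = np.arange(n)
    for i in range(n):
        m = idx != i
        model = fit_lda(X[m], y[m], ridge=ridge)
        d = float(model.decision(X[i:i + 1])[0])
        heldout[i] = d
        preds[i] = model.classes[1] if d > 0 else model.classes[0]
    cv_accuracy = 100.0 * float(np.mean(preds == y))
    return cv_accuracy, heldout, preds


# --------------------------------------------------------------------------
# ROC / AUC

@dataclass
class ROCResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    ci95: tuple[float, float]
    ci_method: str = "delong"


def mann_whitney_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the Mann-Whitney concordance probability (ties = 1/2)."""
    s = np.asarray(scores, float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("both classes must be present")
    pos = s[y == classes[1]]
    m, n = pos.size, s.size - pos.size
    ranks = sps.rankdata(s)
    return float((ranks[y == classes[1]].sum() - m * (m + 1) / 2) / (m * n))


def _delong_ci(scores: np.ndarray, labels: np.ndarray,
               classes) -> tuple[float, tuple[float, float]]:
    """DeLong variance of the Mann-Whitney AUC via placement values."""
    pos = scores[labels == classes[1]]
    neg = scores[labels == classes[0]]
    m, n = pos.size, neg.size
    allr = sps.rankdata(np.concatenate([pos, neg]))
    rp = sps.rankdata(pos)
    rn = sps.rankdata(neg)
    auc = (allr[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (allr[:m] - rp) / n            # placements of positives among negatives
    v01 = 1.0 - (allr[m:] - rn) / m      # placements of negatives among positives
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    se = np.sqrt(s10 / m + s01 / n)
    z = sps.norm.ppf(0.975)
    lo, hi = max(0.0, auc - z * se), min(1.0, auc + z * se)
    return float(auc), (float(lo), float(hi))


def compute_roc(scores: np.ndarray, labels: np.ndarray,
                ci_method: str = "delong", n_boot: int = 2000,
                seed: int = 0) -> ROCResult:
    """Empirical ROC with AUC = Mann-Whitney concordance and a 95% CI.

    ``ci_method`` is ``"delong"`` (default) or ``"bootstrap"``
    (percentile over ``n_boot`` stratified resamples, seeded).
    """
    s = np.asarray(scores, float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("both classes must be present")
    y01 = (y == classes[1]).astype(int)
    fpr, tpr, thr = roc_curve(y01, s)
    auc, ci = _delong_ci(s, y, classes)
    if ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        pos, neg = s[y01 == 1], s[y01 == 0]
        aucs = np.empty(n_boot)
        for b in range(n_boot):
            sp = rng.choice(pos, pos.size)
            sn = rng.choice(neg, neg.size)
            bs = np.concatenate([sn, sp])
            by = np.concatenate([np.zeros(neg.size, int), np.ones(pos.size, int)])
            aucs[b] = mann_whitney_auc(bs, by)
        ci = (float(np.quantile(aucs, 0.025)), float(np.quantile(aucs, 0.975)))
    elif ci_method != "delong":
        raise ValueError("ci_method must be 'delong' or 'bootstrap'")
    return ROCResult(thresholds=thr, sensitivity=tpr, specificity=1 - fpr,
                     auc=auc, ci95=ci, ci_method=ci_method)


# --------------------------------------------------------------------------
# Diagnostic metrics

@dataclass
class MetricsReport:
    """Confusion counts and threshold-specific diagnostics.

    Likelihood ratios are computed from unrounded sensitivity and
    specificity: LR+ = sens/(1-spec) (inf when spec = 1), LR- =
    (1-sens)/spec (nan when spec = 0).
    """

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy_pct: float
    sensitivity_pct: float
    specificity_pct: float
    lr_pos: float
    lr_neg: float
    cv_accuracy_pct: float | None = None

    def to_public_dict(self) -> dict:
        """Rounded the way clinical reports print: whole percents, 2-dp LRs."""
        d = {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "accuracy_pct": round(self.accuracy_pct),
            "sensitivity_pct": round(self.sensitivity_pct),
            "specificity_pct": round(self.specificity_pct),
            "lr_pos": round(self.lr_pos, 2) if np.isfinite(self.lr_pos) else None,
            "lr_neg": round(self.lr_neg, 2) if np.isfinite(self.lr_neg) else None,
        }
        if self.cv_accuracy_pct is not None:
            d["cv_accuracy_pct"] = round(self.cv_accuracy_pct)
        return d


def compute_metrics(predictions: np.ndarray, labels: np.ndarray,
                    positive=None) -> MetricsReport:
    """Confusion counts and sens/spec/LR diagnostics for binary predictions."""
    y = np.asarray(labels)
    p = np.asarray(predictions)
    classes = np.unique(y)
    if positive is None:
        positive = classes[-1]
    yt = y == positive
    yp = p == positive
    tp = int(np.sum(yt & yp))
    fn = int(np.sum(yt & ~yp))
    tn = int(np.sum(~yt & ~yp))
    fp = int(np.sum(~yt & yp))
    total = tp + fp + tn + fn
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    lr_pos = sens / (1 - spec) if spec < 1 else np.inf
    lr_neg = (1 - sens) / spec if spec > 0 else np.nan
    return MetricsReport(tp=tp, fp=fp, tn=tn, fn=fn,
                         accuracy_pct=100.0 * (tp + tn) / total,
                         sensitivity_pct=100.0 * sens,
                         specificity_pct=100.0 * spec,
                         lr_pos=float(lr_pos), lr_neg=float(lr_neg))


# --------------------------------------------------------------------------
# Confounder regression

@dataclass
class RegressionResult:
    """OLS of each component score on clinical covariates."""

    table: pd.DataFrame          # columns: component, term, estimate, p_value
    r_squared: dict[int, float]
    n_used: int
    n_dropped_rows: int
    aliased_terms: tuple[str, ...] = ()


DEFAULT_CONFOUNDERS = ("age", "sex", "bmi", "smoking_status", "pack_years",
                       "fev1_pct_pred")


def confounder_regression(scores: np.ndarray, covariates: pd.DataFrame,
                          covariate_cols=DEFAULT_CONFOUNDERS) -> RegressionResult:
    """Multiple linear regression of each PC score on clinical metadata.

    Complete-case analysis (rows with missing covariates dropped);
    categorical covariates are dummy-coded; rank-deficient (aliased)
    columns are dropped and reported.
    """
    import statsmodels.api as sm

    scores = _colmat(scores)
    cov = covariates.loc[:, list(covariate_cols)].copy()
    mask = cov.notna().all(axis=1).to_numpy()
    n_dropped = int((~mask).sum())
    cov = cov.loc[mask]
    X = pd.get_dummies(cov, drop_first=True, dtype=float)
    X = sm.add_constant(X, has_constant="add")
    aliased: list[str] = []
    keep_cols = ["const"]
    M = X[["const"]].to_numpy()
    for c in X.columns:
        if c == "const":
            continue
        cand = np.column_stack([M, X[c].to_numpy()])
        if np.linalg.matrix_rank(cand) > np.linalg.matrix_rank(M):
            keep_cols.append(c)
            M = cand
        else:
            aliased.append(c)
    X = X[keep_cols]
    rows = []
    r2 = {}
    S = scores[mask]
    for j in range(S.shape[1]):
        fit = sm.OLS(S[:, j], X).fit()
        r2[j + 1] = float(fit.rsquared)
        for term, est, p in zip(X.columns, fit.params, fit.pvalues):
            rows.append({"component": j + 1, "term": term,
                         "estimate": float(est), "p_value": float(p)})
    return RegressionResult(table=pd.DataFrame(rows), r_squared=r2,
                            n_used=int(mask.sum()), n_dropped_rows=n_dropped,
                            aliased_terms=tuple(aliased))
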
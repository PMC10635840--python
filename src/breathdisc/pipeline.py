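"""Orchestration of the study's analyses on a cohort feature table.

Four analyses are wired end-to-end on top of :mod:`breathdisc.stats`:

1. Case-control discrimination (COPD vs lung cancer): PCA fit on a
   stratified 2:1 training split, t-test + bootstrap component
   selection, Fisher discriminant; cross-validated accuracy and ROC/AUC
   on the training set, the frozen model evaluated on the validation
   set, and a combined-set rerun.
2. Prospective detection within COPD: the same machinery restricted to
   baseline COPD measurements with the 2-year incident-cancer flag as
   outcome (LOOCV), plus a baseline screen that applies the frozen
   case-control model to every COPD subject and counts incident cases
   already classified as cancer.
3. Subset analyses: the case-control contrast after excluding
   double-diagnosis (cancer + comorbid COPD) subjects, and the early
   (I-II) vs advanced (III-IV) stage contrast.
4. Confounder regression of component scores on clinical covariates.

Validation subjects never influence standardization, loadings,
component selection, or discriminant weights: every model parameter is
estimated from the training split only and applied frozen.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .core import FEATURE_NAMES
from . import stats as st

__all__ = [
    "AnalysisConfig", "AnalysisReport", "split_cohort",
    "run_case_control", "run_prospective", "run_subset_analyses",
    "run_confounders",
]

SCHEMA_VERSION = "1.0"


@dataclass(frozen=True)
class AnalysisConfig:
    """Settings shared by all analyses."""

    train_fraction: float = 2.0 / 3.0   # 2:1 split
    seed: int = 0
    alpha: float = 0.05
    n_boot: int = 1000
    ci_method: str = "delong"
    bonferroni: bool = False
    #: fit the discriminant on all Kaiser-retained components when no
    #: component passes the t-test (calibration/null runs); the report
    #: still carries the no-discriminating-component status
    fallback_all_retained: bool = False
    #: re-run component selection inside every LOOCV fold instead of
    #: fixing it once on the full set (the default mirrors the study
    #: sequence and is a documented optimism source)
    selection_inside_folds: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass
class AnalysisReport:
    """Result container; ``to_dict`` yields the JSON-serialisable report."""

    analysis: str
    status: str
    config: dict
    results: dict
    models: dict = field(default_factory=dict, repr=False, compare=False)

    def to_dict(self) -> dict:
        return {"schema_version": SCHEMA_VERSION, "analysis": self.analysis,
                "status": self.status, "config": self.config,
                "results": self.results}


def split_cohort(metadata: pd.DataFrame, train_fraction: float = 2.0 / 3.0,
                 seed: int = 0, stratify_col: str = "group"):
    """Stratified random split into training and validation subject ids.

    Each stratum is split to within one subject of ``train_fraction``,
    guaranteeing both groups appear in both sets.  Deterministic under
    ``seed``.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1); the validation "
                         "set may not be empty")
    rng = np.random.default_rng(seed)
    train_ids: list = []
    val_ids: list = []
    for grp, sub in metadata.groupby(stratify_col, sort=True):
        ids = sub["subject_id"].to_numpy()
        if ids.size < 3:
            raise ValueError(f"stratum {grp!r} has fewer than 3 subjects")
        perm = rng.permutation(ids)
        k = int(round(train_fraction * ids.size))
        k = min(max(k, 1), ids.size - 1)
        train_ids.extend(perm[:k])
        val_ids.extend(perm[k:])
    return train_ids, val_ids


def _alignment(features: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """QC-filter and join features with metadata on subject_id."""
    feat = features[features["qc_ok"]] if "qc_ok" in features else features
    merged = metadata.merge(feat, on="subject_id", how="inner",
                            validate="one_to_one")
    return merged.reset_index(drop=True)


def _ttest_block(scores, labels, cfg: AnalysisConfig, seed: int):
    alpha = cfg.alpha / scores.shape[1] if cfg.bonferroni else cfg.alpha
    tests = st.select_components(scores, labels, alpha=alpha)
    support = st.bootstrap_validate(scores, labels, n_boot=cfg.n_boot,
                                    alpha=alpha, seed=seed)
    for tt, s in zip(tests, support):
        tt.bootstrap_support = float(s)
    return tests


def _selected_columns(tests, cfg: AnalysisConfig):
    sel = [t.component - 1 for t in tests if t.selected]
    status = "ok"
    if not sel:
        status = "no_discriminating_component"
        if cfg.fallback_all_retained:
            sel = [t.component - 1 for t in tests]
    return sel, status


def _tests_as_dicts(tests) -> list[dict]:
    return [{"component": t.component, "t": t.t, "p": t.p,
             "selected": t.selected, "bootstrap_support": t.bootstrap_support,
             "flags": list(t.flags)} for t in tests]


def _fit_and_evaluate(scores, labels, cfg: AnalysisConfig, seed: int):
    """Selection + LDA + LOOCV + ROC on one subject set."""
    tests = _ttest_block(scores, labels, cfg, seed)
    sel, status = _selected_columns(tests, cfg)
    block = {"per_component_tests": _tests_as_dicts(tests),
             "selected_components": [c + 1 for c in sel]}
    if not sel:
        return None, tests, status, block
    Xs = scores[:, sel]
    model = st.fit_lda(Xs, labels)
    resub = st.compute_metrics(model.predict(Xs), labels,
                               positive=model.classes[1])
    if cfg.selection_inside_folds:
        cv_acc, heldout, cv_pred = _loocv_with_selection(
            scores, labels, cfg, fallback=sel)
    else:
        cv_acc, heldout, cv_pred = st.loocv(Xs, labels)
    roc = st.compute_roc(heldout, labels, ci_method=cfg.ci_method, seed=seed)
    cv_metrics = st.compute_metrics(cv_pred, labels, positive=model.classes[1])
    block.update({
        "accuracy_pct": resub.accuracy_pct,
        "cv_accuracy_pct": cv_acc,
        "auc": roc.auc, "auc_ci95": list(roc.ci95),
        "cv_metrics": cv_metrics.to_public_dict(),
        "cv_sensitivity_pct": cv_metrics.sensitivity_pct,
        "cv_specificity_pct": cv_metrics.specificity_pct,
        "cv_lr_pos": cv_metrics.lr_pos, "cv_lr_neg": cv_metrics.lr_neg,
    })
    # Youden-optimal operating point of the LOOCV score ROC
    j = roc.sensitivity + roc.specificity - 1.0
    jbest = int(np.argmax(j))
    thr = float(roc.thresholds[jbest])
    ypred = np.where(np.asarray(heldout) >= thr, model.classes[1],
                     model.classes[0])
    youden = st.compute_metrics(ypred, labels, positive=model.classes[1])
    block["youden"] = youden.to_public_dict()
    block["youden_raw"] = {"sensitivity_pct": youden.sensitivity_pct,
                           "specificity_pct": youden.specificity_pct,
                           "lr_pos": youden.lr_pos, "lr_neg": youden.lr_neg}
    extras = {"model": model, "selected": sel, "heldout_scores": heldout}
    return extras, tests, status, block


def _loocv_with_selection(scores, labels, cfg: AnalysisConfig, fallback):
    """LOOCV variant that repeats the t-test selection inside each fold
    (removes the optimism of selecting once on the full set)."""
    y = np.asarray(labels)
    n = scores.shape[0]
    classes = np.unique(y)
    heldout = np.empty(n)
    preds = np.empty(n, dtype=y.dtype)
    idx = np.arange(n)
    for i in range(n):
        m = idx != i
        tests = st.select_components(scores[m], y[m], alpha=cfg.alpha)
        sel = [t.component - 1 for t in tests if t.selected] or list(fallback)
        fold = st.fit_lda(scores[m][:, sel], y[m])
        d = float(fold.decision(scores[i:i + 1, sel])[0])
        heldout[i] = d
        preds[i] = classes[1] if d > 0 else classes[0]
    cv_acc = 100.0 * float(np.mean(preds == y))
    return cv_acc, heldout, preds


def _binary_labels(df: pd.DataFrame) -> np.ndarray:
    """0 = COPD (incl. incident), 1 = lung cancer."""
    return (df["class_label"] == "LUNG_CANCER").astype(int).to_numpy()


def run_case_control(features: pd.DataFrame, metadata: pd.DataFrame,
                     config: AnalysisConfig | None = None) -> AnalysisReport:
    """COPD vs lung cancer: train / frozen-validation / combined analyses."""
    cfg = config or AnalysisConfig()
    data = _alignment(features, metadata)
    data["group"] = np.where(data["class_label"] == "LUNG_CANCER",
                             "LUNG_CANCER", "COPD")
    train_ids, val_ids = split_cohort(data, cfg.train_fraction, cfg.seed)
    tr = data[data["subject_id"].isin(train_ids)].reset_index(drop=True)
    va = data[data["subject_id"].isin(val_ids)].reset_index(drop=True)

    X_tr = tr.loc[:, list(FEATURE_NAMES)]
    y_tr = _binary_labels(tr)
    pca = st.fit_pca(X_tr, subject_ids=tr["subject_id"])
    S_tr = st.project_pca(pca, X_tr)

    extras, tests, status, train_block = _fit_and_evaluate(
        S_tr, y_tr, cfg, cfg.seed)
    results = {
        "n_train": int(len(tr)), "n_validation": int(len(va)),
        "pca": {"retained": pca.retained,
                "eigenvalues": pca.eigenvalues.tolist(),
                "explained_variance_ratio":
                    pca.explained_variance_ratio.tolist()},
        "training": train_block,
    }
    models = {"pca": pca}
    if extras is not None:
        models.update({"lda": extras["model"], "selected": extras["selected"]})
        # frozen model on the independent validation set
        S_va = st.project_pca(pca, va.loc[:, list(FEATURE_NAMES)])
        y_va = _binary_labels(va)
        d_va = extras["model"].decision(S_va[:, extras["selected"]])
        roc_va = st.compute_roc(d_va, y_va, ci_method=cfg.ci_method,
                                seed=cfg.seed)
        m_va = st.compute_metrics((d_va > 0).astype(int), y_va, positive=1)
        results["validation"] = {
            "accuracy_pct": m_va.accuracy_pct,
            "auc": roc_va.auc, "auc_ci95": list(roc_va.ci95),
            "metrics": m_va.to_public_dict(),
        }
    # combined-set rerun: fresh PCA on all subjects
    X_all = data.loc[:, list(FEATURE_NAMES)]
    y_all = _binary_labels(data)
    pca_all = st.fit_pca(X_all, subject_ids=data["subject_id"])
    S_all = st.project_pca(pca_all, X_all)
    extras_all, _, status_all, combined_block = _fit_and_evaluate(
        S_all, y_all, cfg, cfg.seed + 1)
    results["combined"] = combined_block
    if extras_all is not None:
        models["pca_combined"] = pca_all
        models["lda_combined"] = extras_all["model"]
        models["selected_combined"] = extras_all["selected"]
    return AnalysisReport(
        analysis="case_control", status=status,
        config={**asdict(cfg), "train_ids": sorted(map(str, train_ids)),
                "validation_ids": sorted(map(str, val_ids))},
        results=results, models=models)


def run_prospective(features: pd.DataFrame, metadata: pd.DataFrame,
                    config: AnalysisConfig | None = None,
                    case_control: AnalysisReport | None = None) -> AnalysisReport:
    """Incident lung cancer within 2 years among baseline COPD subjects."""
    cfg = config or AnalysisConfig()
    data = _alignment(features, metadata)
    copd = data[data["class_label"] != "LUNG_CANCER"].reset_index(drop=True)
    if "incident_cancer_within_2y" not in copd:
        raise ValueError("metadata lacks 'incident_cancer_within_2y'")
    y = copd["incident_cancer_within_2y"].astype(bool).to_numpy().astype(int)
    if y.sum() == 0:
        raise ValueError("no incident cases in 'incident_cancer_within_2y'")

    X = copd.loc[:, list(FEATURE_NAMES)]
    pca = st.fit_pca(X, subject_ids=copd["subject_id"])
    S = st.project_pca(pca, X)
    extras, tests, status, block = _fit_and_evaluate(S, y, cfg, cfg.seed)
    results = {"n_copd": int(len(copd)), "n_incident": int(y.sum()),
               "incident_fraction_pct": 100.0 * float(y.mean()),
               "pca": {"retained": pca.retained,
                       "eigenvalues": pca.eigenvalues.tolist()},
               "prospective": block}
    models = {"pca": pca}
    if extras is not None:
        models.update({"lda": extras["model"], "selected": extras["selected"],
                       "heldout_scores": extras["heldout_scores"]})

    # baseline screen: frozen case-control model applied to COPD subjects
    if case_control is None:
        case_control = run_case_control(features, metadata, cfg)
    cc = case_control.models
    if "lda" in cc:
        S_cc = st.project_pca(cc["pca"], X)
        pred_cancer = cc["lda"].decision(S_cc[:, cc["selected"]]) > 0
        detected = int(np.sum(pred_cancer & (y == 1)))
        flagged_noninc = int(np.sum(pred_cancer & (y == 0)))
        results["baseline_screen"] = {
            "n_incident": int(y.sum()),
            "detected_at_baseline": detected,
            "detected_pct": 100.0 * detected / y.sum(),
            "noninc_flagged": flagged_noninc,
            "noninc_specificity_pct":
                100.0 * (1 - flagged_noninc / max(int((y == 0).sum()), 1)),
        }
    return AnalysisReport(analysis="prospective", status=status,
                          config=asdict(cfg), results=results, models=models)


def run_subset_analyses(features: pd.DataFrame, metadata: pd.DataFrame,
                        config: AnalysisConfig | None = None) -> AnalysisReport:
    """Comorbid-COPD exclusion rerun and early vs advanced stage contrast."""
    cfg = config or AnalysisConfig()
    data = _alignment(features, metadata)
    results: dict = {}
    models: dict = {}
    status = "ok"

    # (a) combined-set case-control excluding double-diagnosis subjects
    double = (data["class_label"] == "LUNG_CANCER") & \
        data["comorbid_copd"].astype(bool)
    kept = data[~double].reset_index(drop=True)
    results["n_excluded_comorbid"] = int(double.sum())
    X = kept.loc[:, list(FEATURE_NAMES)]
    y = _binary_labels(kept)
    pca = st.fit_pca(X, subject_ids=kept["subject_id"])
    extras, _, st_a, block = _fit_and_evaluate(
        st.project_pca(pca, X), y, cfg, cfg.seed)
    results["comorbid_excluded"] = block
    if extras is not None:
        models["lda_comorbid_excluded"] = extras["model"]

    # (b) early (I-II) vs advanced (III-IV) within incident-cancer subjects
    inc = data[data["incident_cancer_within_2y"].astype(bool)
               & data["stage"].notna()].reset_index(drop=True)
    early = inc["stage"].isin(["I", "II"]).to_numpy()
    if early.sum() >= 3 and (~early).sum() >= 3:
        Xs = inc.loc[:, list(FEATURE_NAMES)]
        ys = (~early).astype(int)  # 1 = advanced
        pca_s = st.fit_pca(Xs, subject_ids=inc["subject_id"])
        extras_s, _, st_b, block_s = _fit_and_evaluate(
            st.project_pca(pca_s, Xs), ys, cfg, cfg.seed)
        results["stage_contrast"] = block_s
        results["stage_contrast"]["n_early"] = int(early.sum())
        results["stage_contrast"]["n_advanced"] = int((~early).sum())
        if extras_s is not None:
            models["lda_stage"] = extras_s["model"]
    else:
        results["stage_contrast"] = {
            "skipped": "a stage stratum has fewer than 3 subjects",
            "n_early": int(early.sum()), "n_advanced": int((~early).sum())}
    return AnalysisReport(analysis="subset", status=status,
                          config=asdict(cfg), results=results, models=models)


def run_confounders(features: pd.DataFrame, metadata: pd.DataFrame,
                    config: AnalysisConfig | None = None) -> AnalysisReport:
    """OLS of every retained component score on the clinical covariates."""
    cfg = config or AnalysisConfig()
    data = _alignment(features, metadata)
    X = data.loc[:, list(FEATURE_NAMES)]
    pca = st.fit_pca(X, subject_ids=data["subject_id"])
    S = st.project_pca(pca, X)
    reg = st.confounder_regression(S, data)
    results = {
        "n_used": reg.n_used, "n_dropped_rows": reg.n_dropped_rows,
        "aliased_terms": list(reg.aliased_terms),
        "r_squared": {str(k): v for k, v in reg.r_squared.items()},
        "coefficients": reg.table.to_dict(orient="records"),
    }
    return AnalysisReport(analysis="confounders", status="ok",
                          config=asdict(cfg), results=results,
                          models={"pca": pca, "regression": reg})
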
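"""Integration of the μFCM score with standard-of-care clinical features.

A maximum-likelihood logistic model combines six standard-of-care (SOC)
predictors — PSA (ng·mL⁻¹, untransformed), age (years), abnormal DRE,
family history, previous negative biopsy, race (black = 1, other = 0) —
with the μFCM model's probability prediction; a six-predictor SOC-only
model serves as the comparator.  The μFCM score entering the combined
model should be the *out-of-fold* CV prediction, never an in-sample one.

Correlated ROC curves are compared with DeLong's method (structural
components); decision cutoffs are anchored at a target sensitivity
(~90% by convention) and reported with the confusion-matrix metrics at
full precision.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm


from evmap.model import CVSpec, make_folds

logger = logging.getLogger(__name__)

SOC_COLUMNS = (
    "psa",
    "age",
    "dre_abnormal",
    "family_history",
    "prior_negative_biopsy",
    "race_black",
)


def _validate_soc(soc: pd.DataFrame) -> pd.DataFrame:
    missing = set(SOC_COLUMNS) - set(soc.columns)
    if missing:
        raise ValueError(f"SOC table missing columns: {sorted(missing)}")
    soc = soc[list(SOC_COLUMNS)].astype(float)
    if soc.isna().any().any():
        raise ValueError("SOC fields must be complete for included patients")
    for col in ("dre_abnormal", "family_history", "prior_negative_biopsy",
                "race_black"):
        if not soc[col].isin([0.0, 1.0]).all():
            raise ValueError(f"{col} must be binary 0/1")
    if (soc["psa"] <= 0).any() or (soc["age"] <= 0).any():
        raise ValueError("psa and age must be positive")
    return soc


@dataclass
class LogisticRiskModel:
    """Fitted logistic model over SOC features (optionally + μFCM score)."""

    coef: np.ndarray  # intercept first
    columns: list[str]
    penalized: bool = False

    def predict_proba(self, soc: pd.DataFrame,
                      mufcm_score: np.ndarray | None = None) -> np.ndarray:
        if "mufcm_score" not in self.columns:
            mufcm_score = None  # model was fit without (or dropped) the score
        X = _design(soc, mufcm_score, log_psa="log_psa" in self.columns)
        expected = ["intercept"] + self.columns
        if X.shape[1] != len(expected):
            raise ValueError(
                f"design has {X.shape[1]} columns, model expects {expected}"
            )
        eta = X @ self.coef
        return 1.0 / (1.0 + np.exp(-eta))


def _design(soc: pd.DataFrame, mufcm_score: np.ndarray | None,
            log_psa: bool = False) -> np.ndarray:
    soc = _validate_soc(soc)
    cols = [np.log(soc["psa"].to_numpy()) if log_psa else soc["psa"].to_numpy()]
    cols += [soc[c].to_numpy() for c in SOC_COLUMNS[1:]]
    if mufcm_score is not None:
        cols.append(np.asarray(mufcm_score, dtype=float))
    X = np.column_stack(cols)
    return np.column_stack([np.ones(len(X)), X])


def fit_combined(
    soc: pd.DataFrame,
    mufcm_score: np.ndarray | None,
    labels: np.ndarray,
    log_psa: bool = False,
) -> LogisticRiskModel:
    """Maximum-likelihood logistic fit of SOC (+ optional μFCM score).

    Pass ``mufcm_score=None`` for the six-predictor SOC-only comparator.
    On (quasi-)separation the fit falls back to a small L2 penalty with a
    logged notice.  ``log_psa`` enters log(PSA) instead of raw PSA.
    """
    import statsmodels.api as sm

    y = np.asarray(labels).astype(int)
    if mufcm_score is not None:
        score = np.asarray(mufcm_score, dtype=float)
        if score.max() == score.min():
            # a constant score is collinear with the intercept and carries
            # no information; the combined model reduces to SOC-only
            logger.warning("constant μFCM score; fitting SOC-only model")
            mufcm_score = None
    X = _design(soc, mufcm_score, log_psa=log_psa)
    columns = (["log_psa" if log_psa else "psa"] + list(SOC_COLUMNS[1:])
               + (["mufcm_score"] if mufcm_score is not None else []))
    penalized = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            coef = np.asarray(res.params)
            if not res.mle_retvals.get("converged", False) or \
                    not np.all(np.isfinite(coef)):
                raise RuntimeError("MLE did not converge (possible separation)")
        except Exception as exc:  # separation, singular design, divergence
            logger.warning("logistic MLE failed (%s); using penalized fit", exc)
            from sklearn.linear_model import LogisticRegression

            lr = LogisticRegression(C=1.0, max_iter=5000)
            lr.fit(X[:, 1:], y)
            coef = np.concatenate([lr.intercept_, lr.coef_.ravel()])
            penalized = True
    return LogisticRiskModel(coef=coef, columns=columns, penalized=penalized)


def cv_combined_scores(
    soc: pd.DataFrame,
    mufcm_score: np.ndarray | None,
    labels: np.ndarray,
    spec: CVSpec | None = None,
    log_psa: bool = False,
) -> np.ndarray:
    """Out-of-fold combined-model probabilities (cross-validated mode).

    The full-cohort fit (:func:`fit_combined`) and this CV mode are both
    available; the CV mode avoids any optimism in the combined AUC.
    """
    spec = spec or CVSpec(repeats=1)
    y = np.asarray(labels).astype(int)
    folds = make_folds(y, spec.folds, spec.base_seed, spec.stratified)
    out = np.full(len(y), np.nan)
    score = None if mufcm_score is None else np.asarray(mufcm_score, float)
    for val_idx in folds:
        train_idx = np.setdiff1d(np.arange(len(y)), val_idx)
        model = fit_combined(
            soc.iloc[train_idx],
            None if score is None else score[train_idx],
            y[train_idx],
            log_psa=log_psa,
        )
        out[val_idx] = model.predict_proba(
            soc.iloc[val_idx], None if score is None else score[val_idx]
        )
    return out


# ---------------------------------------------------------------------------
# DeLong comparison of correlated ROC curves
# ---------------------------------------------------------------------------


def _structural_components(scores: np.ndarray, y: np.ndarray):
    """DeLong V10 (per positive) and V01 (per negative) components."""
    from scipy.stats import rankdata

    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = len(pos), len(neg)
    all_ranks = rankdata(np.concatenate([pos, neg]))
    pos_ranks = rankdata(pos)
    neg_ranks = rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    auc = v10.mean()
    return auc, v10, v01


def delong_variance(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(AUC, DeLong variance of the AUC) for a single ROC curve."""
    y = np.asarray(labels).astype(int)
    auc, v10, v01 = _structural_components(np.asarray(scores, float), y)
    var = (np.var(v10, ddof=1) / len(v10)) + (np.var(v01, ddof=1) / len(v01))
    return float(auc), float(var)


@dataclass
class DeLongResult:
    auc_a: float
    auc_b: float
    delta: float
    se: float
    z: float
    p: float


def delong_compare(
    scores_a: np.ndarray, scores_b: np.ndarray, labels: np.ndarray
) -> DeLongResult:
    """Compare two paired ROC AUCs by DeLong's method.

    The variance of the AUC difference comes from the covariance of the
    structural components; ``z = ΔAUC / SE`` with a two-sided normal
    p-value.  Zero variance (e.g. identical scores) yields p = 1 with a
    warning.
    """
    y = np.asarray(labels).astype(int)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.shape != y.shape:
        raise ValueError("scores_a, scores_b and labels must be paired")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")

    auc_a, v10_a, v01_a = _structural_components(a, y)
    auc_b, v10_b, v01_b = _structural_components(b, y)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.stack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.stack([v01_a, v01_b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    delta = auc_a - auc_b
    if var <= 0:
        logger.warning("DeLong variance is zero; reporting z=0, p=1")
        return DeLongResult(auc_a, auc_b, float(delta), 0.0, 0.0, 1.0)
    se = float(np.sqrt(var))
    z = float(delta / se)
    p = float(2 * norm.sf(abs(z)))
    return DeLongResult(float(auc_a), float(auc_b), float(delta), se, z, p)


# ---------------------------------------------------------------------------
# Cutoffs, confusion metrics, reports
# ---------------------------------------------------------------------------


def confusion_metrics(
    scores: np.ndarray, labels: np.ndarray, cutoff: float
) -> dict[str, float]:
    """Sensitivity/specificity/PPV/NPV for the rule `score ≥ cutoff → positive`."""
    y = np.asarray(labels).astype(int)
    pred = np.asarray(scores, float) >= cutoff
    tp = int(np.sum(pred & (y == 1)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    fp = int(np.sum(pred & (y == 0)))
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    ppv = tp / (tp + fp) if (tp + fp) else float("nan")
    npv = tn / (tn + fn) if (tn + fn) else float("nan")
    return {"tp": tp, "fp": fp, "tn": tn, "fn": fn,
            "sensitivity": sens, "specificity": spec, "ppv": ppv, "npv": npv}


def cutoff_at_sensitivity(
    scores: np.ndarray, labels: np.ndarray, target: float = 0.90
) -> tuple[float, dict[str, float]]:
    """Decision cutoff anchored at a target sensitivity.

    Among cutoffs achieving sensitivity ≥ target, returns the one with the
    highest specificity (ties: the smallest such cutoff), together with its
    confusion metrics.  An unattainable target falls back to a cutoff below
    the minimum score (sensitivity 1) with a warning.
    """
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    candidates = np.unique(s)
    candidates = np.concatenate([candidates, [candidates.max() + 1.0]])
    best_cut, best_metrics = None, None
    for c in candidates:
        m = confusion_metrics(s, y, c)
        if m["sensitivity"] >= target:
            if best_metrics is None or m["specificity"] > best_metrics["specificity"]:
                best_cut, best_metrics = float(c), m
    if best_cut is None:
        logger.warning("sensitivity target %.3f unattainable; using min score", target)
        best_cut = float(s.min())
        best_metrics = confusion_metrics(s, y, best_cut)
    return best_cut, best_metrics


@dataclass
class RiskReport:
    """Per-patient risk probabilities plus the operating point summary."""

    probabilities: np.ndarray
    labels: np.ndarray
    cutoff: float
    metrics: dict[str, float]
    auc: float
    auc_ci: tuple[float, float]
    roc_points: pd.DataFrame = field(default_factory=pd.DataFrame)

    @classmethod
    def build(
        cls, scores: np.ndarray, labels: np.ndarray, sensitivity_target: float = 0.90
    ) -> "RiskReport":
        from sklearn.metrics import roc_curve

        y = np.asarray(labels).astype(int)
        s = np.asarray(scores, dtype=float)
        cutoff, metrics = cutoff_at_sensitivity(s, y, sensitivity_target)
        auc, var = delong_variance(s, y)
        half = 1.959963984540054 * np.sqrt(max(var, 0.0))
        fpr, tpr, thr = roc_curve(y, s)
        roc_df = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
        return cls(
            probabilities=s,
            labels=y,
            cutoff=cutoff,
            metrics=metrics,
            auc=auc,
            auc_ci=(max(0.0, auc - half), min(1.0, auc + half)),
            roc_points=roc_df,
        )


def waterfall_export(
    report: RiskReport,
    out_prefix: str | Path,
    patient_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Sorted per-patient bars of predicted risk relative to the cutoff.

    Writes ``<prefix>.csv`` and ``<prefix>.png``; returns the sorted table
    (one row per patient, monotone in probability).
    """
    out_prefix = Path(out_prefix)
    n = len(report.probabilities)
    ids = list(patient_ids) if patient_ids is not None else [str(i) for i in range(n)]
    df = pd.DataFrame({
        "patient_id": ids,
        "probability": report.probabilities,
        "label": report.labels,
    })
    df = df.sort_values("probability", kind="stable").reset_index(drop=True)
    df["above_cutoff"] = df["probability"] >= report.cutoff
    df.to_csv(out_prefix.with_suffix(".csv"), index=False)

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3.5))
    colors = np.where(df["label"] == 1, "#c0392b", "#2980b9")
    ax.bar(np.arange(n), df["probability"] - report.cutoff, color=colors, width=1.0)
    ax.axhline(0, color="k", lw=0.8)
    ax.set_xlabel("patients (sorted by predicted risk)")
    ax.set_ylabel("probability − cutoff")
    ax.set_title(f"cutoff = {report.cutoff:.6g}")
    fig.tight_layout()
    fig.savefig(out_prefix.with_suffix(".png"), dpi=100)
    plt.close(fig)
    return df
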
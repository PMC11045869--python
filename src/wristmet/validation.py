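"""Held-out validation battery for the MET estimator.

Covers the full method-comparison toolkit used to validate wearable
energy-expenditure estimators against indirect calorimetry:

* per-category classification: sensitivity/specificity with Wilson 95% CIs,
  the Youden index J = sens + spec − 1, and ROC AUC with a DeLong variance
  and normal-approximation CI, plus an unpaired z-test for comparing AUCs
  between independent cohorts (adults vs children);
* MET error metrics: MAE, MAPE, RMSE, pooled and per-participant;
* agreement: Bland–Altman bias and 95% limits of agreement, and the
  two-way random-effects absolute-agreement single-measures ICC(2,1);
* Spearman rank correlation.

Classification is evaluated per category with the estimated MET as the
continuous ROC score (negated for SED, where *lower* METs indicate the
positive state) and the categorized estimate as the operating point.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .met_model import (
    DEFAULT_THRESHOLDS,
    HierarchicalMetModel,
    IntensityThresholds,
    build_design,
)
from .synthetic_trials import ParticipantProfile, TrialMinute

ROC_CATEGORIES = ("SED", "MVPA", "VPA")


class UndefinedMetricError(ValueError):
    """A metric has no defined value on this input (single-class truth, ...)."""


class LeakageError(ValueError):
    """Train and test participants overlap."""


# ---------------------------------------------------------------------------
# classification

def binarize_by_category(
    mets: Sequence[float] | np.ndarray,
    category: str,
    thresholds: IntensityThresholds = DEFAULT_THRESHOLDS,
) -> np.ndarray:
    """0/1 labels for one intensity state.

    SED is positive at or below the sedentary cut-point; MVPA and VPA are
    positive at or above the moderate and vigorous cut-points respectively.
    """
    mets = np.asarray(mets, dtype=float)
    if not np.all(mets > 0):
        raise ValueError("METs must be positive")
    if category == "SED":
        return (mets <= thresholds.sed_max).astype(int)
    if category == "MVPA":
        return (mets > thresholds.lpa_max).astype(int)
    if category == "VPA":
        return (mets > thresholds.mpa_max).astype(int)
    raise ValueError(f"unknown ROC category {category!r}")


def youden_index(sensitivity: float, specificity: float) -> float:
    """J = sensitivity + specificity − 1."""
    return sensitivity + specificity - 1.0


@dataclass(frozen=True)
class ConfusionMetrics:
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    youden: float
    tp: int
    fn: int
    tn: int
    fp: int


def confusion_metrics(
    true_binary: Sequence[int] | np.ndarray, pred_binary: Sequence[int] | np.ndarray
) -> ConfusionMetrics:
    """Sensitivity, specificity (Wilson 95% CIs) and Youden J at one
    operating point."""
    t = np.asarray(true_binary).astype(int)
    p = np.asarray(pred_binary).astype(int)
    if t.shape != p.shape:
        raise ValueError("true and predicted labels must have equal length")
    if len(np.unique(t)) < 2:
        raise UndefinedMetricError(
            "sensitivity/specificity need both classes present in truth"
        )
    tp = int(np.sum((t == 1) & (p == 1)))
    fn = int(np.sum((t == 1) & (p == 0)))
    tn = int(np.sum((t == 0) & (p == 0)))
    fp = int(np.sum((t == 0) & (p == 1)))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    sens_ci = proportion_confint(tp, tp + fn, alpha=0.05, method="wilson")
    spec_ci = proportion_confint(tn, tn + fp, alpha=0.05, method="wilson")
    return ConfusionMetrics(
        sensitivity=sens,
        sensitivity_ci=(float(sens_ci[0]), float(sens_ci[1])),
        specificity=spec,
        specificity_ci=(float(spec_ci[0]), float(spec_ci[1])),
        youden=youden_index(sens, spec),
        tp=tp,
        fn=fn,
        tn=tn,
        fp=fp,
    )


@dataclass(frozen=True)
class AucResult:
    auc: float
    variance: float
    ci: tuple[float, float]
    n_pos: int
    n_neg: int


def roc_auc(
    true_binary: Sequence[int] | np.ndarray, scores: Sequence[float] | np.ndarray
) -> AucResult:
    """AUC by the Mann–Whitney concordance estimator (ties ½) with the
    DeLong placement variance and a normal 95% CI clipped to [0, 1].

    Scores are oriented so that higher means more likely positive.
    """
    t = np.asarray(true_binary).astype(int)
    s = np.asarray(scores, dtype=float)
    if t.shape != s.shape:
        raise ValueError("labels and scores must have equal length")
    pos = s[t == 1]
    neg = s[t == 0]
    m, n = pos.size, neg.size
    if m == 0 or n == 0:
        raise UndefinedMetricError("AUC needs both classes present in truth")
    ranks_all = stats.rankdata(np.concatenate([pos, neg]))
    # placements: per-observation concordance fractions against the other class
    v10 = (ranks_all[:m] - stats.rankdata(pos)) / n
    v01 = 1.0 - (ranks_all[m:] - stats.rankdata(neg)) / m
    auc = float(np.mean(v10))
    s10 = float(np.var(v10, ddof=1)) if m > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if n > 1 else 0.0
    variance = s10 / m + s01 / n
    half = 1.959963984540054 * np.sqrt(variance)
    ci = (float(max(auc - half, 0.0)), float(min(auc + half, 1.0)))
    return AucResult(auc=auc, variance=variance, ci=ci, n_pos=m, n_neg=n)


def compare_auc(a: AucResult, b: AucResult) -> tuple[float, float]:
    """Unpaired z-test for two AUCs from independent samples.

    Returns (z, two-sided p).  With zero pooled variance the p-value is 1.0
    for identical AUCs and 0.0 otherwise.
    """
    diff = a.auc - b.auc
    pooled = a.variance + b.variance
    if pooled == 0.0:
        return (0.0, 1.0) if diff == 0.0 else (np.inf, 0.0)
    z = diff / np.sqrt(pooled)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


# ---------------------------------------------------------------------------
# agreement / error

@dataclass(frozen=True)
class ErrorMetrics:
    """Pooled errors with the SD of the per-minute error magnitudes as the
    '±' companion, plus per-participant summaries (mean ± SD across
    participants)."""

    mae: float
    mae_sd: float
    mape: float  # percent
    mape_sd: float
    rmse: float
    rmse_sd: float
    participant_mae_mean: float
    participant_mae_sd: float
    participant_rmse_mean: float
    participant_rmse_sd: float


def error_metrics(
    true_mets: Sequence[float] | np.ndarray,
    est_mets: Sequence[float] | np.ndarray,
    participant_ids: Sequence[str] | None = None,
) -> ErrorMetrics:
    t = np.asarray(true_mets, dtype=float)
    e = np.asarray(est_mets, dtype=float)
    if t.shape != e.shape:
        raise ValueError("true and estimated METs must have equal length")
    if not np.all(t > 0):
        raise ValueError("true METs must be positive")
    abs_err = np.abs(e - t)
    pct_err = abs_err / t * 100.0
    if participant_ids is not None:
        pids = np.asarray(participant_ids)
        uniq = np.unique(pids)
        p_mae = np.array([abs_err[pids == u].mean() for u in uniq])
        p_rmse = np.array([np.sqrt((abs_err[pids == u] ** 2).mean()) for u in uniq])
    else:
        p_mae = p_rmse = np.array([np.nan])
    sd = lambda a: float(np.std(a, ddof=1)) if a.size > 1 else 0.0
    return ErrorMetrics(
        mae=float(abs_err.mean()),
        mae_sd=sd(abs_err),
        mape=float(pct_err.mean()),
        mape_sd=sd(pct_err),
        rmse=float(np.sqrt((abs_err**2).mean())),
        rmse_sd=sd(abs_err),
        participant_mae_mean=float(p_mae.mean()),
        participant_mae_sd=sd(p_mae),
        participant_rmse_mean=float(p_rmse.mean()),
        participant_rmse_sd=sd(p_rmse),
    )


def bland_altman(
    true_mets: Sequence[float] | np.ndarray,
    est_mets: Sequence[float] | np.ndarray,
) -> tuple[float, float, float]:
    """Bias and 95% limits of agreement of d = estimated − true.

    LoA = bias ± 1.96·SD(d) with the sample SD (n−1), so the LoA midpoint is
    identically the bias.
    """
    t = np.asarray(true_mets, dtype=float)
    e = np.asarray(est_mets, dtype=float)
    if t.shape != e.shape or t.size < 2:
        raise UndefinedMetricError("Bland–Altman needs >= 2 paired values")
    d = e - t
    bias = float(d.mean())
    half = 1.96 * float(np.std(d, ddof=1))
    return bias, bias - half, bias + half


def icc(
    true_mets: Sequence[float] | np.ndarray, est_mets: Sequence[float] | np.ndarray
) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    Each minute is a subject rated by two 'raters' (criterion and estimate);
    the coefficient is built from the row/column/error mean squares:
    (MSR − MSE) / (MSR + (k−1)·MSE + k·(MSC − MSE)/n).
    """
    t = np.asarray(true_mets, dtype=float)
    e = np.asarray(est_mets, dtype=float)
    if t.shape != e.shape or t.size < 2:
        raise UndefinedMetricError("ICC needs >= 2 paired values")
    data = np.column_stack([t, e])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise UndefinedMetricError("ICC undefined: zero total variance")
    return float((msr - mse) / denom)


def spearman_corr(
    true_mets: Sequence[float] | np.ndarray, est_mets: Sequence[float] | np.ndarray
) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) and its p-value."""
    t = np.asarray(true_mets, dtype=float)
    e = np.asarray(est_mets, dtype=float)
    if t.shape != e.shape or t.size < 3:
        raise UndefinedMetricError("Spearman correlation needs >= 3 pairs")
    if np.all(t == t[0]) or np.all(e == e[0]):
        raise UndefinedMetricError("Spearman correlation undefined for constant input")
    rho, p = stats.spearmanr(t, e)
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# full report

@dataclass(frozen=True)
class ClassificationMetrics:
    category: str
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    youden: float
    auc: float
    auc_ci: tuple[float, float]
    auc_variance: float
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class AgreementMetrics:
    mae: float
    mae_sd: float
    mape: float
    mape_sd: float
    rmse: float
    rmse_sd: float
    participant_mae_mean: float
    participant_mae_sd: float
    participant_rmse_mean: float
    participant_rmse_sd: float
    bias: float
    loa_low: float
    loa_high: float
    icc: float
    spearman_rho: float
    spearman_p: float
    true_median: float
    true_iqr: tuple[float, float]
    est_median: float
    est_iqr: tuple[float, float]


@dataclass(frozen=True)
class ValidationReport:
    group: str
    n_participants: int
    n_minutes: int
    classification: dict[str, ClassificationMetrics]
    agreement: AgreementMetrics
    auc_comparison: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    def to_text(self) -> str:
        lines = [
            f"Validation report — group: {self.group}",
            f"participants: {self.n_participants}   minutes: {self.n_minutes}",
            "",
            f"{'':14s}{'SED':>18s}{'MVPA':>18s}{'VPA':>18s}",
        ]

        def row(label, fmt):
            cells = [fmt(self.classification[c]) for c in ROC_CATEGORIES]
            lines.append(f"{label:14s}" + "".join(f"{c:>18s}" for c in cells))

        row("Sensitivity", lambda m: f"{m.sensitivity * 100:.1f}")
        row(
            "  95% CI",
            lambda m: f"{m.sensitivity_ci[0] * 100:.1f}-{m.sensitivity_ci[1] * 100:.1f}",
        )
        row("Specificity", lambda m: f"{m.specificity * 100:.1f}")
        row(
            "  95% CI",
            lambda m: f"{m.specificity_ci[0] * 100:.1f}-{m.specificity_ci[1] * 100:.1f}",
        )
        row("Youden index", lambda m: f"{m.youden:.2f}")
        row("AUC", lambda m: f"{m.auc:.2f}")
        row("  95% CI", lambda m: f"{m.auc_ci[0]:.2f}-{m.auc_ci[1]:.2f}")
        a = self.agreement
        lines += [
            "",
            f"Estimated METs (median, IQR): {a.est_median:.2f}, "
            f"{a.est_iqr[0]:.2f}-{a.est_iqr[1]:.2f}",
            f"True METs (median, IQR):      {a.true_median:.2f}, "
            f"{a.true_iqr[0]:.2f}-{a.true_iqr[1]:.2f}",
            f"MAE:  {a.mae:.2f} ± {a.mae_sd:.2f} METs",
            f"MAPE: {a.mape:.2f} ± {a.mape_sd:.2f} %",
            f"RMSE: {a.rmse:.2f} ± {a.rmse_sd:.2f} METs",
            f"Bias (est − true): {a.bias:.2f}  95% LoA: {a.loa_low:.2f} to "
            f"{a.loa_high:.2f}",
            f"ICC(2,1): {a.icc:.2f}",
            f"Spearman rho: {a.spearman_rho:.2f} (p = {a.spearman_p:.3g})",
        ]
        return "\n".join(lines)


def evaluate(
    model: HierarchicalMetModel,
    test_minutes: Sequence[TrialMinute],
    participants: Sequence[ParticipantProfile],
) -> ValidationReport:
    """Run the estimator on every test minute and compute the full battery.

    Raises :class:`LeakageError` if any test participant contributed to the
    model fit.  The ROC score for each category is the continuous estimated
    MET (negated for SED); sensitivity/specificity are taken at the
    categorized-estimate operating point.
    """
    test_pids = {m.participant_id for m in test_minutes}
    overlap = test_pids & set(model.train_participants)
    if overlap:
        raise LeakageError(
            f"participants in both training and test sets: {sorted(overlap)}"
        )
    X, true_mets, pids = build_design(test_minutes, participants)
    _, est_mets = model.predict_batch(X)

    thresholds = model.thresholds
    classification: dict[str, ClassificationMetrics] = {}
    for category in ROC_CATEGORIES:
        truth = binarize_by_category(true_mets, category, thresholds)
        pred = binarize_by_category(est_mets, category, thresholds)
        score = -est_mets if category == "SED" else est_mets
        cm = confusion_metrics(truth, pred)
        auc = roc_auc(truth, score)
        classification[category] = ClassificationMetrics(
            category=category,
            sensitivity=cm.sensitivity,
            sensitivity_ci=cm.sensitivity_ci,
            specificity=cm.specificity,
            specificity_ci=cm.specificity_ci,
            youden=cm.youden,
            auc=auc.auc,
            auc_ci=auc.ci,
            auc_variance=auc.variance,
            n_pos=auc.n_pos,
            n_neg=auc.n_neg,
        )

    errs = error_metrics(true_mets, est_mets, pids)
    bias, loa_low, loa_high = bland_altman(true_mets, est_mets)
    rho, p = spearman_corr(true_mets, est_mets)
    q = lambda a: (float(np.quantile(a, 0.25)), float(np.quantile(a, 0.75)))
    agreement = AgreementMetrics(
        mae=errs.mae,
        mae_sd=errs.mae_sd,
        mape=errs.mape,
        mape_sd=errs.mape_sd,
        rmse=errs.rmse,
        rmse_sd=errs.rmse_sd,
        participant_mae_mean=errs.participant_mae_mean,
        participant_mae_sd=errs.participant_mae_sd,
        participant_rmse_mean=errs.participant_rmse_mean,
        participant_rmse_sd=errs.participant_rmse_sd,
        bias=bias,
        loa_low=loa_low,
        loa_high=loa_high,
        icc=icc(true_mets, est_mets),
        spearman_rho=rho,
        spearman_p=p,
        true_median=float(np.median(true_mets)),
        true_iqr=q(true_mets),
        est_median=float(np.median(est_mets)),
        est_iqr=q(est_mets),
    )
    return ValidationReport(
        group=model.group,
        n_participants=len(test_pids),
        n_minutes=len(test_minutes),
        classification=classification,
        agreement=agreement,
    )


def compare_reports(a: ValidationReport, b: ValidationReport) -> dict[str, float]:
    """Per-category p-values for AUC differences between two independent
    cohorts (e.g. adults vs children)."""
    out = {}
    for category in ROC_CATEGORIES:
        ma, mb = a.classification[category], b.classification[category]
        _, p = compare_auc(
            AucResult(ma.auc, ma.auc_variance, ma.auc_ci, ma.n_pos, ma.n_neg),
            AucResult(mb.auc, mb.auc_variance, mb.auc_ci, mb.n_pos, mb.n_neg),
        )
        out[category] = p
    return out
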
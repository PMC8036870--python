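"""Agreement and classification metrics for estimated vs. reference rates."""
from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from scipy import stats

__all__ = [
    "RRMetrics",
    "ClassificationMetrics",
    "pr_tolerance_bpm",
    "rr_metrics",
    "classification_metrics",
    "percentage_time_used",
]


def pr_tolerance_bpm(window_s: float = 8.0) -> float:
    """Rate-agreement tolerance implied by the analysis-window length.

    Half the spectral bin width of a rectangular window of ``window_s``
    seconds, in breaths per minute: (60 / window_s) / 2 = 3.75 BPM for 8 s.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    return (60.0 / window_s) / 2.0


@dataclass
class RRMetrics:
    mae_bpm: float
    rmse_bpm: float
    pr_pct: float
    bias_bpm: float
    loa_low_bpm: float
    loa_high_bpm: float
    pearson_r: float
    n: int

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ClassificationMetrics:
    accuracy_pct: float
    balanced_accuracy_pct: float
    sensitivity_pct: float
    specificity_pct: float
    tp: int
    fp: int
    fn: int
    tn: int

    def to_dict(self) -> dict:
        return asdict(self)


def rr_metrics(est, ref, tolerance: float | None = None) -> RRMetrics:
    """Paired rate-agreement metrics in BPM.

    PR counts |error| <= tolerance (inclusive; default 3.75 BPM).
    Bland-Altman uses the sample standard deviation (ddof=1) and the 1.96
    normal quantile. Pearson r is NaN for fewer than 2 pairs or a constant
    input.
    """
    est = np.asarray(est, float)
    ref = np.asarray(ref, float)
    if est.shape != ref.shape or est.ndim != 1:
        raise ValueError("est and ref must be equal-length 1-D arrays")
    if est.size == 0:
        raise ValueError("empty input")
    if tolerance is None:
        tolerance = pr_tolerance_bpm()
    err = est - ref
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    pr = 100.0 * float(np.mean(np.abs(err) <= tolerance))
    bias = float(np.mean(err))
    sd = float(np.std(err, ddof=1)) if est.size > 1 else np.nan
    if est.size > 1 and np.std(est) > 0 and np.std(ref) > 0:
        rho = float(stats.pearsonr(est, ref).statistic)
    else:
        rho = np.nan
    return RRMetrics(
        mae_bpm=mae,
        rmse_bpm=rmse,
        pr_pct=pr,
        bias_bpm=bias,
        loa_low_bpm=bias - 1.96 * sd,
        loa_high_bpm=bias + 1.96 * sd,
        pearson_r=rho,
        n=int(est.size),
    )


def classification_metrics(predicted, truth) -> ClassificationMetrics:
    """Window-classification metrics with type-1 motion as the positive class.

    ``predicted`` and ``truth`` are boolean-like (True = type-1 motion);
    excluded windows must be removed beforehand. A rate whose class is
    absent from ``truth`` is reported as NaN, and balanced accuracy then
    equals the defined rate.
    """
    predicted = np.asarray(predicted, bool)
    truth = np.asarray(truth, bool)
    if predicted.shape != truth.shape or predicted.ndim != 1:
        raise ValueError("predicted and truth must be equal-length 1-D arrays")
    if predicted.size == 0:
        raise ValueError("empty input")
    tp = int((predicted & truth).sum())
    fp = int((predicted & ~truth).sum())
    fn = int((~predicted & truth).sum())
    tn = int((~predicted & ~truth).sum())
    sens = 100.0 * tp / (tp + fn) if (tp + fn) else np.nan
    spec = 100.0 * tn / (tn + fp) if (tn + fp) else np.nan
    defined = [r for r in (sens, spec) if not np.isnan(r)]
    bal = float(np.mean(defined)) if defined else np.nan
    acc = 100.0 * (tp + tn) / predicted.size
    return ClassificationMetrics(
        accuracy_pct=acc,
        balanced_accuracy_pct=bal,
        sensitivity_pct=sens,
        specificity_pct=spec,
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
    )


def percentage_time_used(motion_flags, included_mask=None) -> float:
    """PT: percent of included windows the motion detector deems usable.

    ``motion_flags`` holds 1 for type-1 windows, 0 for usable;
    ``included_mask`` (default: all) restricts the denominator, e.g. to
    windows annotated as containing only type-2 motion.
    """
    flags = np.asarray(motion_flags, int)
    if included_mask is None:
        included_mask = np.ones(flags.shape, bool)
    included_mask = np.asarray(included_mask, bool)
    n_inc = int(included_mask.sum())
    if n_inc == 0:
        raise ValueError("no included windows")
    usable = int(((flags == 0) & included_mask).sum())
    return 100.0 * usable / n_inc
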
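"""Gross-motion detection and window classification.

A window is declared unusable (type-1 motion: movement involving the
chest/torso that hides respiration) when the fraction of "moving" pixels in
any frame difference of any view reaches ``thr2``. A pixel counts as moving
when its absolute frame-to-frame change exceeds ``thr1 = Range(X) / f1``,
with the range taken over all pixels and frames of the window (so the
detector is invariant to intensity gain).

``(f1, thr2)`` are optimized by leave-one-subject-out cross-validation on
balanced accuracy with type-1 motion as the positive class.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .preprocess import WindowView

__all__ = [
    "EXCLUDED",
    "TYPE1",
    "USABLE",
    "EXCLUDED_LABELS",
    "MovingPixelSeries",
    "MotionParams",
    "WindowLabel",
    "MotionSubject",
    "CVResult",
    "moving_pixel_ratio",
    "classify_window",
    "ground_truth_windows",
    "balanced_accuracy_score",
    "optimize_params",
]

EXCLUDED = "excluded"
TYPE1 = "type1_motion"
USABLE = "usable"

#: Annotation-track columns that force a window into the excluded class
#: (caregiver/parent interventions; baby out of bed, someone in the
#: background, camera motion, unsuitable view).
EXCLUDED_LABELS = ("intervention", "other")
#: Annotation-track column marking type-1 motion frames.
TYPE1_LABEL = "type1"


@dataclass
class MotionParams:
    f1: float = 8.0
    thr2: float = 0.005

    def __post_init__(self) -> None:
        if self.f1 <= 0:
            raise ValueError("f1 must be positive")
        if not 0.0 <= self.thr2 <= 1.0:
            raise ValueError("thr2 must lie in [0, 1]")


@dataclass
class MovingPixelSeries:
    """Binary moving-pixel maps and their per-difference-sample ratios."""

    maps: np.ndarray  # (n-1, rows, cols) bool
    ratio: np.ndarray  # (n-1,) fraction of moving pixels per difference frame
    thr1: float


@dataclass
class WindowLabel:
    window_index: int
    label: str


def moving_pixel_ratio(window: WindowView | np.ndarray, f1: float) -> MovingPixelSeries:
    """Compute the moving-pixel maps and ratio series of one window.

    ``thr1 = Range(X) / f1`` where Range(X) is max - min over every pixel of
    every frame in the window. A pixel moves when its absolute difference
    between consecutive frames is strictly greater than thr1. A constant
    window has thr1 = 0, so any nonzero difference counts as moving
    (degenerate but documented behaviour).
    """
    samples = window.samples if isinstance(window, WindowView) else np.asarray(window, float)
    if samples.ndim != 3 or len(samples) < 2:
        raise ValueError("window must hold at least 2 frames of shape (rows, cols)")
    if f1 <= 0:
        raise ValueError("f1 must be positive")
    thr1 = float(samples.max() - samples.min()) / f1
    dof = np.abs(np.diff(samples, axis=0))
    maps = dof > thr1
    ratio = maps.mean(axis=(1, 2))
    return MovingPixelSeries(maps=maps, ratio=ratio, thr1=thr1)


def classify_window(
    series: Sequence[MovingPixelSeries | np.ndarray], thr2: float
) -> int:
    """Return 1 (type-1 motion) iff any view has any ratio sample >= thr2."""
    series = list(series)
    if len(series) == 0:
        raise ValueError("need at least one moving-pixel series")
    for s in series:
        ratio = s.ratio if isinstance(s, MovingPixelSeries) else np.asarray(s, float)
        if np.any(ratio >= thr2):
            return 1
    return 0


def ground_truth_windows(
    annotations: pd.DataFrame, windows: Sequence[WindowView]
) -> list[WindowLabel]:
    """Label windows from a per-frame annotation track.

    Priority: a window containing at least one excluded frame is excluded;
    otherwise one type-1 frame makes it type-1; otherwise it is usable
    (type-2 motion, NNS and stillness are all usable).
    """
    if "frame_index" not in annotations.columns:
        raise ValueError("annotations must have a frame_index column")
    ann = annotations.set_index("frame_index")
    excluded_cols = [c for c in EXCLUDED_LABELS if c in ann.columns]
    has_type1 = TYPE1_LABEL in ann.columns
    labels = []
    for w in windows:
        idx = w.frame_indices
        missing = np.setdiff1d(idx, ann.index.to_numpy())
        if len(missing):
            raise ValueError(f"frames without annotation: {missing[:5]}...")
        rows = ann.loc[idx]
        if excluded_cols and rows[excluded_cols].to_numpy().any():
            label = EXCLUDED
        elif has_type1 and rows[TYPE1_LABEL].to_numpy().any():
            label = TYPE1
        else:
            label = USABLE
        labels.append(WindowLabel(window_index=w.index, label=label))
    return labels


# ---------------------------------------------------------------------------
# Parameter optimization (leave-one-subject-out cross-validation)
# ---------------------------------------------------------------------------


@dataclass
class MotionSubject:
    """Per-subject material for the parameter optimization.

    ``view_windows[v][j]`` is the raw sample array (n, rows, cols) of window
    ``j`` in view ``v``; ``labels[j]`` is the ground-truth class of window
    ``j`` (excluded / type1_motion / usable).
    """

    name: str
    view_windows: Sequence[Sequence[np.ndarray]]
    labels: Sequence[str]

    def __post_init__(self) -> None:
        n = len(self.labels)
        for v, wins in enumerate(self.view_windows):
            if len(wins) != n:
                raise ValueError(f"view {v} has {len(wins)} windows, expected {n}")


@dataclass
class CVResult:
    chosen: tuple[float, float]
    fold_candidates: list[tuple[float, float]]
    fold_scores: list[np.ndarray]  # (n_f1, n_thr2) balanced accuracy per fold
    fold_confusion: list[dict]  # held-out confusion at the fold candidate
    degenerate_folds: list[bool]  # True where only one class was present


def balanced_accuracy_score(
    predicted: np.ndarray, truth: np.ndarray
) -> tuple[float, bool]:
    """Balanced accuracy with type-1 (True) as the positive class.

    When only one class is present in ``truth`` the defined rate alone is
    returned, with a degeneracy flag.
    """
    predicted = np.asarray(predicted, bool)
    truth = np.asarray(truth, bool)
    pos, neg = truth.sum(), (~truth).sum()
    sens = (predicted & truth).sum() / pos if pos else np.nan
    spec = (~predicted & ~truth).sum() / neg if neg else np.nan
    if pos and neg:
        return float((sens + spec) / 2.0), False
    if pos or neg:
        return float(sens if pos else spec), True
    raise ValueError("no windows to score")


def _max_ratio_tensor(
    subject: MotionSubject, grid_f1: Sequence[float]
) -> np.ndarray:
    """Max moving-pixel ratio per (f1, window, view).

    Classification only depends on the per-window maximum of s(u), so the
    whole grid can be scored from this tensor.
    """
    n_views = len(subject.view_windows)
    n_win = len(subject.labels)
    out = np.zeros((len(grid_f1), n_win, n_views))
    for v in range(n_views):
        for j in range(n_win):
            samples = np.asarray(subject.view_windows[v][j], float)
            rng = float(samples.max() - samples.min())
            dof = np.abs(np.diff(samples, axis=0))
            for i, f1 in enumerate(grid_f1):
                out[i, j, v] = (dof > rng / f1).mean(axis=(1, 2)).max()
    return out


def _best_grid_point(
    scores: np.ndarray, grid_f1: Sequence[float], grid_thr2: Sequence[float]
) -> tuple[float, float]:
    """Argmax with the deterministic tie rule: smallest thr2, then smallest f1."""
    best = np.nanmax(scores)
    ties = np.argwhere(scores >= best - 1e-12)
    order = sorted(ties, key=lambda ij: (grid_thr2[ij[1]], grid_f1[ij[0]]))
    i, j = order[0]
    return float(grid_f1[i]), float(grid_thr2[j])


def optimize_params(
    subjects: Sequence[MotionSubject],
    grid_f1: Sequence[float],
    grid_thr2: Sequence[float],
) -> CVResult:
    """Leave-one-subject-out optimization of (f1, thr2).

    For each held-out subject every grid point is scored on the remaining
    subjects (excluded windows removed) by balanced accuracy; the fold
    candidate is the argmax and the returned set is the modal candidate
    across folds. Ties use the smallest-thr2-then-smallest-f1 rule.
    """
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    grid_f1 = list(grid_f1)
    grid_thr2 = list(grid_thr2)
    tensors = [_max_ratio_tensor(s, grid_f1) for s in subjects]
    truths = [np.array([lab == TYPE1 for lab in s.labels]) for s in subjects]
    keeps = [np.array([lab != EXCLUDED for lab in s.labels]) for s in subjects]

    fold_candidates, fold_scores, fold_confusion, degenerate = [], [], [], []
    for held in range(len(subjects)):
        train = [k for k in range(len(subjects)) if k != held]
        truth = np.concatenate([truths[k][keeps[k]] for k in train])
        scores = np.full((len(grid_f1), len(grid_thr2)), np.nan)
        fold_flag = False
        for i in range(len(grid_f1)):
            smax = np.concatenate(
                [tensors[k][i][keeps[k]] for k in train], axis=0
            )  # (windows, views)
            for j, thr2 in enumerate(grid_thr2):
                pred = (smax >= thr2).any(axis=1)
                scores[i, j], flag = balanced_accuracy_score(pred, truth)
                fold_flag = fold_flag or flag
        cand = _best_grid_point(scores, grid_f1, grid_thr2)
        fold_candidates.append(cand)
        fold_scores.append(scores)
        degenerate.append(fold_flag)

        # held-out confusion at the fold candidate
        i, j = grid_f1.index(cand[0]), grid_thr2.index(cand[1])
        pred = (tensors[held][i][keeps[held]] >= grid_thr2[j]).any(axis=1)
        truth_h = truths[held][keeps[held]]
        fold_confusion.append(
            {
                "tp": int((pred & truth_h).sum()),
                "fp": int((pred & ~truth_h).sum()),
                "fn": int((~pred & truth_h).sum()),
                "tn": int((~pred & ~truth_h).sum()),
            }
        )

    counts = Counter(fold_candidates)
    top = max(counts.values())
    modal = [c for c, n in counts.items() if n == top]
    chosen = sorted(modal, key=lambda c: (c[1], c[0]))[0]
    return CVResult(
        chosen=chosen,
        fold_candidates=fold_candidates,
        fold_scores=fold_scores,
        fold_confusion=fold_confusion,
        degenerate_folds=degenerate,
    )
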
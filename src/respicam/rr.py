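"""Respiration-rate estimation from usable windows.

Per window, three per-pixel features are fused to find a "core" respiration
pixel without any manual region of interest:

* pseudo-periodicity ``Q``: normalized spectral peak height of the
  first-differenced pixel series,
* frequency clusters ``W``: a nonlinear 3x3 filter rewarding pixels whose
  dominant frequency matches their neighbours (with harmonic disambiguation
  and suppression of rates at/above the band's upper limit),
* gradient ``G``: binary edge map of the window-average image (respiration
  motion is only visible at intensity edges).

Pixels correlating with the core above ``kappa3`` (after band-pass
filtering) are averaged into the respiratory signal, whose windowed,
zero-padded spectral peak gives the rate. The same spectral path serves the
reference waveform, and the per-window spectra stack into an STFT.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy.signal import butter, find_peaks, sosfiltfilt

from .preprocess import FrameStack, WindowView, resample_uniform, sliding_windows

__all__ = [
    "SpectralContext",
    "FeatureMaps",
    "PixelSelection",
    "WindowAnalysis",
    "pixel_spectra",
    "pseudo_periodicity",
    "dominant_frequency",
    "cluster_filter",
    "gradient_feature",
    "normalize01",
    "fuse_and_pick_core",
    "bandpass",
    "select_pixels",
    "windowed_spectrum",
    "spectrum_peak_bpm",
    "estimate_rr",
    "analyze_window",
    "reference_rr",
    "build_stft",
]


@dataclass(frozen=True)
class SpectralContext:
    """Frequency-grid bookkeeping shared by every spectral operation.

    For 8 s windows at 9 Hz: N = 72 samples, Nz = 120 * 72 = 8640 padded
    samples, and a half grid of Nz/2 bins spaced 1/(Nz * Ts) Hz apart.
    """

    n_samples: int = 72
    ts: float = 1.0 / 9.0
    pad_factor: int = 120
    lim1: float = 0.5
    lim2: float = 1.83
    bandpass_order: int = 4

    def __post_init__(self) -> None:
        if self.n_samples < 4:
            raise ValueError("need at least 4 samples per window")
        nyquist = 0.5 / self.ts
        if not 0.0 < self.lim1 < self.lim2 < nyquist:
            raise ValueError("require 0 < lim1 < lim2 < Nyquist")

    @property
    def nz(self) -> int:
        return self.pad_factor * self.n_samples

    @property
    def n_bins(self) -> int:
        return self.nz // 2

    @property
    def freqs(self) -> np.ndarray:
        return np.arange(self.n_bins) / (self.nz * self.ts)

    @property
    def bin_hz(self) -> float:
        return 1.0 / (self.nz * self.ts)

    @property
    def harmonic_tol_hz(self) -> float:
        """Tolerance for the harmonic-position check: 1/(N*Ts) (0.125 Hz)."""
        return 1.0 / (self.n_samples * self.ts)

    def band_mask(self, inclusive: bool = False) -> np.ndarray:
        f = self.freqs
        if inclusive:
            return (f >= self.lim1) & (f <= self.lim2)
        return (f > self.lim1) & (f < self.lim2)


@dataclass
class FeatureMaps:
    Q: np.ndarray
    RRhat: np.ndarray
    W: np.ndarray
    G: np.ndarray
    V: np.ndarray


@dataclass
class PixelSelection:
    core: tuple[int, int]
    members: np.ndarray  # (k, 2) row/col indices, includes the core
    correlations: np.ndarray  # (k,)
    filtered: np.ndarray  # (n_samples, k) band-passed member series


@dataclass
class WindowAnalysis:
    rr_bpm: float | None
    spectrum: np.ndarray | None
    quality_ok: bool
    core: tuple[int, int] | None
    n_selected: int
    features: FeatureMaps


def pixel_spectra(
    samples: np.ndarray, ctx: SpectralContext, differential: bool = True
) -> np.ndarray:
    """Magnitude spectra of every pixel series on the half grid.

    With ``differential`` each series is first-differenced (length N-1) to
    attenuate low frequencies. The (filtered) series is multiplied by a
    symmetric Hanning window of its own length, zero-padded to Nz and
    transformed; bins k = 0 .. Nz/2 - 1 are returned with shape
    ``(n_pixels, n_bins)``.
    """
    samples = np.asarray(samples, float)
    if samples.ndim == 3:
        flat = samples.reshape(len(samples), -1)
    elif samples.ndim == 2:
        flat = samples
    else:
        flat = samples[:, None]
    if len(flat) < 4:
        raise ValueError("need at least 4 samples")
    if differential:
        flat = np.diff(flat, axis=0)
    win = np.hanning(len(flat))
    spec = np.abs(np.fft.rfft(flat * win[:, None], n=ctx.nz, axis=0))
    return spec[: ctx.n_bins].T


def pseudo_periodicity(spectra: np.ndarray) -> np.ndarray:
    """Normalized spectral peak height per pixel: max|y'| / sqrt(sum |y'|^2).

    Lies in [0, 1]; an all-zero spectrum maps to 0.
    """
    spectra = np.atleast_2d(np.asarray(spectra, float))
    peak = spectra.max(axis=1)
    energy = np.sqrt((spectra**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        q = peak / energy
    return np.where(energy > 0, q, 0.0)


def _band_local_maxima(
    spec: np.ndarray, lo: int, hi: int
) -> np.ndarray:
    """Indices of local maxima of one spectrum inside [lo, hi].

    A peak is a bin strictly greater than both neighbours; plateaus take
    their lowest index. Neighbours just outside the band participate in the
    comparison.
    """
    seg_lo = max(lo - 1, 0)
    seg = spec[seg_lo : hi + 2]
    _, props = find_peaks(seg, plateau_size=1)
    idx = props["left_edges"] + seg_lo
    return idx[(idx >= lo) & (idx <= hi)]


def dominant_frequency(
    y_diff: np.ndarray, y_plain: np.ndarray, ctx: SpectralContext
) -> np.ndarray:
    """Per-pixel dominant respiratory frequency with harmonic disambiguation.

    ``h`` holds the in-band (lim1 < f < lim2) local-maximum frequencies of
    the differential spectrum, ascending. The lowest peak h(1) is taken as
    the rate when some later peak sits within 1/(N*Ts) of 2*h(1) and looks
    like a first harmonic (smaller in the plain spectrum, at least as large
    in the differential one -- i.e. only differentiation promoted it);
    otherwise the global argmax of the differential spectrum is used.
    Rates at or above lim2 are suppressed to 0.

    Returns a flat array of rates (Hz) aligned with the pixel axis of the
    input spectra.
    """
    y_diff = np.atleast_2d(y_diff)
    y_plain = np.atleast_2d(y_plain)
    if y_diff.shape != y_plain.shape:
        raise ValueError("filtered and plain spectra must share a shape")
    freqs = ctx.freqs
    band = np.flatnonzero(ctx.band_mask())
    lo, hi = int(band[0]), int(band[-1])
    tol = ctx.harmonic_tol_hz
    global_arg = y_diff.argmax(axis=1)  # argmax ties resolve to lowest bin
    rr = freqs[global_arg].copy()
    for p in range(len(y_diff)):
        pk = _band_local_maxima(y_diff[p], lo, hi)
        if len(pk) < 2:
            continue
        i1 = pk[0]
        near = np.abs(freqs[pk[1:]] - 2.0 * freqs[i1]) < tol
        for iz in pk[1:][near]:
            if y_plain[p, iz] < y_plain[p, i1] and y_diff[p, iz] >= y_diff[p, i1]:
                rr[p] = freqs[i1]
                break
    return np.where(rr < ctx.lim2, rr, 0.0)


def cluster_filter(rr_hat: np.ndarray, kappa1: float = 70.0) -> np.ndarray:
    """3x3 nonlinear neighbourhood filter mapping frequency clusters.

    w = (1/9) * sum over the neighbourhood of exp(-kappa1 * |rr_c - rr_n| /
    rr_c). Pixels whose own rate was suppressed to 0 produce non-finite
    terms and get w = 0 (this is what rejects type-2-motion regions and
    high-frequency oscillations); border pixels get w = 0.
    """
    rr_hat = np.asarray(rr_hat, float)
    if rr_hat.ndim != 2:
        raise ValueError("rr_hat must be a 2-D map")
    rows, cols = rr_hat.shape
    w = np.zeros_like(rr_hat)
    if rows < 3 or cols < 3:
        return w
    center = rr_hat[1:-1, 1:-1]
    acc = np.zeros_like(center)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                nb = rr_hat[1 + dr : rows - 1 + dr, 1 + dc : cols - 1 + dc]
                acc += np.exp(-kappa1 * np.abs(center - nb) / center)
    acc = np.where(center > 0, acc / 9.0, 0.0)
    w[1:-1, 1:-1] = np.nan_to_num(acc, nan=0.0)
    return w


def gradient_feature(samples: np.ndarray, kappa2: float = 16.0) -> np.ndarray:
    """Binary edge map of the window-average image.

    g = 1 where the spatial gradient magnitude of the mean frame exceeds
    Range(A)/kappa2, with Range(A) over all pixels and frames of the window.
    Central differences interior, one-sided at borders. A constant window
    (range 0, gradient 0) yields all zeros.
    """
    samples = np.asarray(samples, float)
    mean_img = samples.mean(axis=0)
    gr, gc = np.gradient(mean_img)
    mag = np.hypot(gr, gc)
    rng = float(samples.max() - samples.min())
    return (mag > rng / kappa2).astype(np.uint8)


def normalize01(x: np.ndarray) -> np.ndarray:
    """Min-max normalization to [0, 1]; a constant map becomes all zeros."""
    x = np.asarray(x, float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def fuse_and_pick_core(
    Q: np.ndarray, W: np.ndarray, G: np.ndarray
) -> tuple[np.ndarray, tuple[int, int] | None]:
    """Multiply the min-max-normalized features and take the argmax pixel.

    Returns ``(V, core)``; ``core`` is None when V is identically zero (the
    window is then flagged low-quality and no rate is emitted). Argmax ties
    resolve to the lowest (row, col).
    """
    if Q.shape != W.shape or Q.shape != G.shape:
        raise ValueError("feature maps must share a shape")
    V = normalize01(Q) * normalize01(W) * normalize01(G)
    if not np.any(V > 0):
        return V, None
    core = np.unravel_index(int(V.argmax()), V.shape)
    return V, (int(core[0]), int(core[1]))


@lru_cache(maxsize=8)
def _bandpass_sos(order: int, lim1: float, lim2: float, fs: float):
    return butter(order, (lim1, lim2), btype="bandpass", fs=fs, output="sos")


def bandpass(series: np.ndarray, ctx: SpectralContext) -> np.ndarray:
    """Zero-phase Butterworth band-pass over [lim1, lim2] along axis 0.

    Applied forward-backward so correlation signs and lags are preserved.
    """
    sos = _bandpass_sos(ctx.bandpass_order, ctx.lim1, ctx.lim2, 1.0 / ctx.ts)
    return sosfiltfilt(sos, np.asarray(series, float), axis=0)


def select_pixels(
    samples: np.ndarray,
    core: tuple[int, int],
    ctx: SpectralContext,
    kappa3: float = 0.9,
) -> PixelSelection:
    """Collect every pixel whose band-passed series correlates with the
    core's above ``kappa3`` in absolute value.

    Zero-variance filtered series have undefined correlation and are
    excluded. The core itself is always a member (c = 1) unless its own
    filtered series is degenerate.
    """
    samples = np.asarray(samples, float)
    n, rows, cols = samples.shape
    filt = bandpass(samples.reshape(n, -1), ctx)
    core_flat = core[0] * cols + core[1]
    ref = filt[:, core_flat]
    centered = filt - filt.mean(axis=0)
    norms = np.sqrt((centered**2).sum(axis=0))
    r0 = centered[:, core_flat]
    s0 = norms[core_flat]
    with np.errstate(divide="ignore", invalid="ignore"):
        c = (centered * r0[:, None]).sum(axis=0) / (norms * s0)
    valid = np.isfinite(c) & (norms > 0) & (s0 > 0)
    c = np.where(valid, c, 0.0)
    mask = valid & (np.abs(c) > kappa3)
    if s0 > 0:
        mask[core_flat] = True
        c[core_flat] = 1.0
    members = np.column_stack(np.unravel_index(np.flatnonzero(mask), (rows, cols)))
    return PixelSelection(
        core=core,
        members=members,
        correlations=c[mask],
        filtered=filt[:, mask],
    )


def windowed_spectrum(series: np.ndarray, ctx: SpectralContext) -> np.ndarray:
    """Hanning-window a real series, zero-pad to Nz, return |DFT| half grid."""
    series = np.asarray(series, float)
    w = series * np.hanning(len(series))
    return np.abs(np.fft.rfft(w, n=ctx.nz))[: ctx.n_bins]


def spectrum_peak_bpm(
    spectrum: np.ndarray, ctx: SpectralContext, band_limited: bool = False
) -> float | None:
    """60 x the frequency of the spectral peak (lowest bin wins ties).

    With ``band_limited`` the search is restricted to [lim1, lim2]
    inclusive; otherwise the band-pass filtering applied upstream already
    confines the peak. Returns None for an all-zero spectrum.
    """
    spectrum = np.asarray(spectrum, float)
    if band_limited:
        mask = ctx.band_mask(inclusive=True)
        idx = np.flatnonzero(mask)
        seg = spectrum[idx]
    else:
        idx = np.arange(len(spectrum))
        seg = spectrum
    if seg.size == 0 or seg.max() <= 0:
        return None
    k = idx[int(seg.argmax())]
    return 60.0 * ctx.freqs[k]


def estimate_rr(
    selection: PixelSelection, ctx: SpectralContext, band_limited: bool = False
) -> tuple[float | None, np.ndarray | None]:
    """Average the selected band-passed series and read the spectral peak.

    Returns ``(bpm, spectrum)``; both None for an empty selection.
    """
    if selection.filtered.shape[1] == 0:
        return None, None
    combined = selection.filtered.mean(axis=1)
    spec = windowed_spectrum(combined, ctx)
    return spectrum_peak_bpm(spec, ctx, band_limited=band_limited), spec


def analyze_window(
    samples: np.ndarray,
    ctx: SpectralContext,
    kappa1: float = 70.0,
    kappa2: float = 16.0,
    kappa3: float = 0.9,
    band_limited: bool = False,
) -> WindowAnalysis:
    """Run the full single-window chain: features -> core -> selection -> RR."""
    samples = np.asarray(samples, float)
    n, rows, cols = samples.shape
    y_diff = pixel_spectra(samples, ctx, differential=True)
    y_plain = pixel_spectra(samples, ctx, differential=False)
    Q = pseudo_periodicity(y_diff).reshape(rows, cols)
    rr_hat = dominant_frequency(y_diff, y_plain, ctx).reshape(rows, cols)
    W = cluster_filter(rr_hat, kappa1)
    G = gradient_feature(samples, kappa2)
    V, core = fuse_and_pick_core(Q, W, G)
    features = FeatureMaps(Q=Q, RRhat=rr_hat, W=W, G=G, V=V)
    if core is None:
        return WindowAnalysis(None, None, False, None, 0, features)
    selection = select_pixels(samples, core, ctx, kappa3)
    bpm, spec = estimate_rr(selection, ctx, band_limited=band_limited)
    ok = bpm is not None
    return WindowAnalysis(bpm, spec, ok, core, selection.filtered.shape[1], features)


def reference_rr(
    timestamps: np.ndarray,
    values: np.ndarray,
    ctx: SpectralContext,
    window_s: float = 8.0,
    slide_s: float = 1.0,
    band_limited: bool = False,
) -> list[dict]:
    """Per-window reference rate from a respiration waveform.

    The waveform is linearly resampled to the video rate and processed with
    the identical spectral path as the video signal (band-pass, Hanning,
    zero-pad, peak). Constant windows yield ``bpm = None``.

    Returns one dict per window: window_index, start_s, bpm.
    """
    stack = FrameStack(
        frames=np.asarray(values, float)[:, None, None],
        timestamps=np.asarray(timestamps, float),
        view_id=0,
    )
    uniform = resample_uniform(stack, 1.0 / ctx.ts)
    rows = []
    for w in sliding_windows(uniform, window_s=window_s, slide_s=slide_s):
        series = w.samples[:, 0, 0]
        if np.ptp(series) == 0:
            rows.append({"window_index": w.index, "start_s": w.start_s, "bpm": None})
            continue
        filt = bandpass(series, ctx)
        spec = windowed_spectrum(filt, ctx)
        bpm = spectrum_peak_bpm(spec, ctx, band_limited=band_limited)
        rows.append({"window_index": w.index, "start_s": w.start_s, "bpm": bpm})
    return rows


def build_stft(
    spectra: Sequence[np.ndarray | None], ctx: SpectralContext
) -> np.ndarray:
    """Stack per-window spectra into a (windows x bins) matrix.

    Windows with no spectrum (motion, excluded, low quality, gaps) become
    all-NaN rows so the time axis stays aligned with the window indices.
    """
    out = np.full((len(spectra), ctx.n_bins), np.nan)
    for i, spec in enumerate(spectra):
        if spec is not None:
            out[i] = spec
    return out
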
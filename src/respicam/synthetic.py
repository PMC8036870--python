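"""Seeded synthetic recordings with the statistical structure the method assumes.

A scene is a noisy baseline image carrying a spatially contiguous breathing
cluster (a sinusoid, optionally with a first harmonic, on top of a static
intensity step so the edge feature fires), plus optional scheduled events:

* type-1: a large fraction of the frame jumps frame-to-frame (chest/torso
  motion hiding respiration),
* type-2: a transient intensity ramp in a small region (limb/head motion),
* NNS: a region oscillating at its own -- typically supra-band -- frequency,
* excluded: interval stamped with an intervention/other annotation.

Every recording comes with a frame-level annotation track, a 62.5 Hz
reference waveform and per-window ground truth, so all pipeline stages are
testable without clinical data. All randomness flows from one seed; event
noise uses independent streams so adding an event never perturbs the
background draws.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .motion import EXCLUDED, TYPE1, USABLE
from .preprocess import FrameStack, expected_window_count

__all__ = [
    "ClusterSpec",
    "Type1Event",
    "Type2Event",
    "NNSEvent",
    "ExcludedEvent",
    "SceneSpec",
    "SyntheticRecording",
    "generate",
    "make_multiview",
    "scene_from_dict",
]

ANNOTATION_COLUMNS = ("still", "type1", "type2", "nns", "intervention", "other")


@dataclass
class ClusterSpec:
    """A rectangular breathing-pixel cluster.

    ``region`` is (row_start, row_stop, col_start, col_stop). The cluster
    adds ``edge_step`` as a static offset (creating edges at its boundary)
    and oscillates as a*[sin(2 pi f t) + harmonic_fraction * sin(4 pi f t)].
    """

    region: tuple[int, int, int, int] = (20, 40, 30, 55)
    rr_bpm: float = 40.0
    amplitude: float = 1.0
    harmonic_fraction: float = 0.0
    edge_step: float = 5.0


@dataclass
class Type1Event:
    start_s: float
    duration_s: float
    area_fraction: float = 0.02
    magnitude: float = 20.0
    views: tuple[int, ...] | None = None  # None = all views


@dataclass
class Type2Event:
    start_s: float
    duration_s: float
    region: tuple[int, int, int, int] = (2, 6, 2, 6)
    magnitude: float = 3.0
    views: tuple[int, ...] | None = None


@dataclass
class NNSEvent:
    freq_hz: float = 2.5
    amplitude: float = 1.0
    region: tuple[int, int, int, int] = (2, 8, 2, 8)
    start_s: float = 0.0
    duration_s: float | None = None  # None = whole recording
    views: tuple[int, ...] | None = None


@dataclass
class ExcludedEvent:
    start_s: float
    duration_s: float
    kind: str = "intervention"  # or "other"


@dataclass
class SceneSpec:
    shape: tuple[int, int] = (60, 80)
    duration_s: float = 30.0
    rate_hz: float = 9.0
    baseline: float = 30.0
    #: peak-to-peak intensity of a static smooth ramp across the frame. Real
    #: scenes have structure whose range dwarfs the sensor noise; without it
    #: thr1 = Range(X)/f1 would sit at noise level and flag everything.
    background_contrast: float = 10.0
    noise_sigma: float = 0.05
    cluster: ClusterSpec | None = field(default_factory=ClusterSpec)
    events: Sequence = ()
    non_uniform: bool = False
    mean_rate_hz: float = 8.7  # used when non_uniform (jittered acquisition)
    reference_rate_hz: float = 62.5
    reference_noise_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        rows, cols = self.shape
        regions = []
        if self.cluster is not None:
            regions.append(self.cluster.region)
        for ev in self.events:
            if hasattr(ev, "region"):
                regions.append(ev.region)
        for r0, r1, c0, c1 in regions:
            if not (0 <= r0 < r1 <= rows and 0 <= c0 < c1 <= cols):
                raise ValueError(f"region {(r0, r1, c0, c1)} outside frame {self.shape}")
        if self.duration_s <= 0 or self.rate_hz <= 0:
            raise ValueError("duration and rate must be positive")


@dataclass
class SyntheticRecording:
    stacks: list[FrameStack]
    annotations: pd.DataFrame
    reference_t: np.ndarray
    reference_values: np.ndarray
    truth: pd.DataFrame
    spec: SceneSpec


def _event_active(t: np.ndarray, start: float, duration: float) -> np.ndarray:
    return (t >= start) & (t < start + duration)


def _in_view(ev, view: int) -> bool:
    views = getattr(ev, "views", None)
    return views is None or view in views


def _timestamps(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    if not spec.non_uniform:
        n = int(round(spec.duration_s * spec.rate_hz))
        return np.arange(n) / spec.rate_hz
    # jittered acquisition around the mean frame rate
    dt = 1.0 / spec.mean_rate_hz
    dts = dt * (1.0 + rng.uniform(-0.2, 0.2, size=int(spec.duration_s * spec.mean_rate_hz * 1.2)))
    t = np.concatenate([[0.0], np.cumsum(dts)])
    return t[t <= spec.duration_s]


def _render_view(
    spec: SceneSpec,
    t: np.ndarray,
    view: int,
    noise_rng: np.random.Generator,
    event_rng: np.random.Generator,
    cluster_views: tuple[int, ...],
) -> np.ndarray:
    rows, cols = spec.shape
    rr_grid, cc_grid = np.meshgrid(
        np.linspace(0.0, 1.0, rows), np.linspace(0.0, 1.0, cols), indexing="ij"
    )
    static = spec.baseline + spec.background_contrast * 0.5 * (rr_grid + cc_grid)
    frames = static[None] + noise_rng.normal(0.0, spec.noise_sigma, size=(len(t), rows, cols))
    if spec.cluster is not None and view in cluster_views:
        cl = spec.cluster
        r0, r1, c0, c1 = cl.region
        f = cl.rr_bpm / 60.0
        osc = cl.amplitude * (
            np.sin(2 * np.pi * f * t) + cl.harmonic_fraction * np.sin(4 * np.pi * f * t)
        )
        frames[:, r0:r1, c0:c1] += cl.edge_step + osc[:, None, None]
    for ev in spec.events:
        if isinstance(ev, Type1Event) and _in_view(ev, view):
            active = np.flatnonzero(_event_active(t, ev.start_s, ev.duration_s))
            n_px = max(1, math.ceil(ev.area_fraction * rows * cols))
            flat = event_rng.choice(rows * cols, size=n_px, replace=False)
            rr, cc = np.unravel_index(flat, (rows, cols))
            for k in active:
                sign = 0.5 if k % 2 == 0 else -0.5
                frames[k, rr, cc] += sign * ev.magnitude
        elif isinstance(ev, Type2Event) and _in_view(ev, view):
            r0, r1, c0, c1 = ev.region
            # triangular bump: ramp up to the magnitude mid-event, back down
            rel = (t - ev.start_s) / ev.duration_s
            profile = np.clip(1.0 - np.abs(2.0 * rel - 1.0), 0.0, 1.0)
            profile[~_event_active(t, ev.start_s, ev.duration_s)] = 0.0
            frames[:, r0:r1, c0:c1] += (ev.magnitude * profile)[:, None, None]
        elif isinstance(ev, NNSEvent) and _in_view(ev, view):
            r0, r1, c0, c1 = ev.region
            dur = ev.duration_s if ev.duration_s is not None else spec.duration_s
            active = _event_active(t, ev.start_s, dur)
            osc = ev.amplitude * np.sin(2 * np.pi * ev.freq_hz * t) * active
            frames[:, r0:r1, c0:c1] += osc[:, None, None]
    return frames


def _annotations(spec: SceneSpec, t: np.ndarray) -> pd.DataFrame:
    n = len(t)
    cols = {name: np.zeros(n, dtype=int) for name in ANNOTATION_COLUMNS}
    for ev in spec.events:
        if isinstance(ev, Type1Event):
            cols["type1"] |= _event_active(t, ev.start_s, ev.duration_s).astype(int)
        elif isinstance(ev, Type2Event):
            cols["type2"] |= _event_active(t, ev.start_s, ev.duration_s).astype(int)
        elif isinstance(ev, NNSEvent):
            dur = ev.duration_s if ev.duration_s is not None else spec.duration_s
            cols["nns"] |= _event_active(t, ev.start_s, dur).astype(int)
        elif isinstance(ev, ExcludedEvent):
            cols[ev.kind] |= _event_active(t, ev.start_s, ev.duration_s).astype(int)
    cols["still"] = ((cols["type1"] | cols["type2"]) == 0).astype(int)
    out = pd.DataFrame({"frame_index": np.arange(n), "timestamp_s": t, **cols})
    return out


def _truth(spec: SceneSpec, window_s: float = 8.0, slide_s: float = 1.0) -> pd.DataFrame:
    """Per-window ground truth on the uniform target grid."""
    n_win = expected_window_count(spec.duration_s, window_s, slide_s)
    rows = []
    for j in range(n_win):
        start = j * slide_s
        end = start + window_s
        label = USABLE
        for ev in spec.events:
            if isinstance(ev, ExcludedEvent) and start < ev.start_s + ev.duration_s and end > ev.start_s:
                label = EXCLUDED
                break
        if label == USABLE:
            for ev in spec.events:
                if isinstance(ev, Type1Event) and start < ev.start_s + ev.duration_s and end > ev.start_s:
                    label = TYPE1
                    break
        rows.append(
            {
                "window_index": j + 1,
                "start_s": start,
                "rr_true_bpm": spec.cluster.rr_bpm if spec.cluster else np.nan,
                "label": label,
            }
        )
    return pd.DataFrame(rows)


def generate(spec: SceneSpec) -> SyntheticRecording:
    """Render a single-view recording from a scene description."""
    return make_multiview(spec, n_views=1)


def make_multiview(
    spec: SceneSpec, n_views: int = 3, cluster_views: tuple[int, ...] | None = None
) -> SyntheticRecording:
    """Render ``n_views`` synchronized views sharing the event schedule.

    Noise is drawn independently per view; the breathing cluster appears in
    ``cluster_views`` (default: view 0 only for multi-view scenes, so the
    cluster is visible in at least one view).
    """
    if n_views < 1:
        raise ValueError("n_views must be >= 1")
    if cluster_views is None:
        cluster_views = tuple(range(n_views)) if n_views == 1 else (0,)
    seq = np.random.SeedSequence(spec.seed)
    # fixed stream layout: timestamps, reference, events, then one per view
    children = seq.spawn(3 + n_views)
    ts_rng = np.random.default_rng(children[0])
    ref_rng = np.random.default_rng(children[1])
    t = _timestamps(spec, ts_rng)

    stacks = []
    for v in range(n_views):
        # event placement stream keyed on (seed, view): independent of the
        # noise streams so adding/removing events never shifts other draws
        event_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=spec.seed, spawn_key=(2, v))
        )
        noise_rng = np.random.default_rng(children[3 + v])
        frames = _render_view(spec, t, v, noise_rng, event_rng, cluster_views)
        stacks.append(FrameStack(frames=frames, timestamps=t.copy(), view_id=v))

    ref_t = np.arange(int(spec.duration_s * spec.reference_rate_hz)) / spec.reference_rate_hz
    if spec.cluster is not None:
        f = spec.cluster.rr_bpm / 60.0
        ref_v = np.sin(2 * np.pi * f * ref_t)
    else:
        ref_v = np.zeros_like(ref_t)
    ref_v = ref_v + ref_rng.normal(0.0, spec.reference_noise_sigma, size=ref_t.shape)

    return SyntheticRecording(
        stacks=stacks,
        annotations=_annotations(spec, t),
        reference_t=ref_t,
        reference_values=ref_v,
        truth=_truth(spec),
        spec=spec,
    )


# ---------------------------------------------------------------------------
# YAML/JSON scene descriptions
# ---------------------------------------------------------------------------

_EVENT_TYPES = {
    "type1": Type1Event,
    "type2": Type2Event,
    "nns": NNSEvent,
    "excluded": ExcludedEvent,
}


def scene_from_dict(data: dict) -> SceneSpec:
    """Build a SceneSpec from a plain dict (parsed YAML/JSON)."""
    data = dict(data)
    if "cluster" in data and data["cluster"] is not None:
        cl = dict(data["cluster"])
        if "region" in cl:
            cl["region"] = tuple(cl["region"])
        data["cluster"] = ClusterSpec(**cl)
    events = []
    for ev in data.pop("events", []):
        ev = dict(ev)
        kind = ev.pop("kind")
        if "region" in ev:
            ev["region"] = tuple(ev["region"])
        if "views" in ev and ev["views"] is not None:
            ev["views"] = tuple(ev["views"])
        events.append(_EVENT_TYPES[kind](**ev))
    data["events"] = tuple(events)
    if "shape" in data:
        data["shape"] = tuple(data["shape"])
    return SceneSpec(**data)
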
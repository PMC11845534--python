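"""Velocity-based saccade/fixation parsing with an adaptive median threshold.

The detector follows the classic adaptive velocity algorithm: gaze velocity
is a 5-sample weighted central difference, the per-axis noise level is the
median-based SD ``sigma = sqrt(median(v^2) - median(v)^2)``, and a saccade
is a run of at least ``min_saccade_samples`` consecutive samples whose
velocity exceeds the elliptic threshold
``(vx/eta_x)^2 + (vy/eta_y)^2 > 1`` with ``eta = lambda * sigma``
(``lambda`` defaults to 6 SDs above the subject median). Fixations are the
complementary intervals, split at gaze gaps, then filtered to the
150–2000 ms range (bounds inclusive), labelled with the majority AOI of
their raw samples, and annotated with the amplitude of the immediately
preceding saccade.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AOI_CONDITIONS, GazeStream, empty_events, validate_events

__all__ = [
    "DetectionParams",
    "VelocityTrace",
    "compute_velocity",
    "detect_saccades",
    "derive_fixations",
    "filter_fixations",
    "assign_aoi",
    "attach_prior_saccade",
    "detect_events",
]


@dataclass
class DetectionParams:
    lambda_multiplier: float = 6.0
    min_saccade_samples: int = 4
    smoothing_span: int = 5
    min_fix_ms: float = 150.0
    max_fix_ms: float = 2000.0

    def __post_init__(self) -> None:
        if self.lambda_multiplier <= 0:
            raise ValueError("lambda_multiplier must be positive")
        if self.min_saccade_samples < 1:
            raise ValueError("min_saccade_samples must be >= 1")
        if not self.min_fix_ms < self.max_fix_ms:
            raise ValueError("min_fix_ms must be below max_fix_ms")


@dataclass
class VelocityTrace:
    """Gaze velocity with per-axis adaptive thresholds.

    Velocity samples adjacent to gaps or stream edges are NaN and can never
    be suprathreshold, so saccade runs cannot span gaps.
    """

    vx: np.ndarray
    vy: np.ndarray
    eta_x: float
    eta_y: float
    rate: float
    x: np.ndarray
    y: np.ndarray
    t: np.ndarray


def _median_sd(v: np.ndarray) -> float:
    """Median-based robust SD: sqrt(median(v^2) - median(v)^2)."""
    v = v[np.isfinite(v)]
    return float(np.sqrt(max(np.median(v * v) - np.median(v) ** 2, 0.0)))


def compute_velocity(gaze: GazeStream,
                     params: DetectionParams | None = None) -> VelocityTrace:
    """5-sample weighted central-difference velocity plus noise thresholds.

    ``v_i = (p_{i+2} + p_{i+1} - p_{i-1} - p_{i-2}) / (6 dt)`` per axis.
    Raises on degenerate (constant-position) input where the median-based
    SD vanishes.
    """
    params = params or DetectionParams()
    n = len(gaze)
    if n < params.smoothing_span:
        raise ValueError(f"need at least {params.smoothing_span} samples, got {n}")
    dt = 1.0 / gaze.rate
    vx = np.full(n, np.nan)
    vy = np.full(n, np.nan)
    x, y = gaze.x, gaze.y
    vx[2:-2] = (x[4:] + x[3:-1] - x[1:-3] - x[:-4]) / (6 * dt)
    vy[2:-2] = (y[4:] + y[3:-1] - y[1:-3] - y[:-4]) / (6 * dt)
    # the centred difference skips the middle sample; a gap sample must
    # still break detection runs
    gap = gaze.gap_mask
    vx[gap] = np.nan
    vy[gap] = np.nan

    sx, sy = _median_sd(vx), _median_sd(vy)
    if not np.isfinite(sx) or not np.isfinite(sy) or sx < 1e-12 or sy < 1e-12:
        raise ValueError(
            "degenerate gaze trace: median-based velocity SD is zero; "
            "cannot form an adaptive threshold"
        )
    lam = params.lambda_multiplier
    return VelocityTrace(vx, vy, lam * sx, lam * sy, gaze.rate, x, y, gaze.t)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open (start, stop) index pairs."""
    padded = np.concatenate([[False], mask, [False]])
    diff = np.diff(padded.astype(int))
    starts = np.flatnonzero(diff == 1)
    stops = np.flatnonzero(diff == -1)
    return list(zip(starts, stops))


def detect_saccades(vel: VelocityTrace,
                    params: DetectionParams | None = None) -> pd.DataFrame:
    """Saccades as maximal suprathreshold runs of minimum length.

    Amplitude is the endpoint-to-endpoint Euclidean displacement; onsets
    are EEG sample indices derived from the gaze timestamps.
    """
    params = params or DetectionParams()
    if not (np.isfinite(vel.eta_x) and np.isfinite(vel.eta_y)
            and vel.eta_x > 0 and vel.eta_y > 0):
        raise ValueError("velocity thresholds must be finite and positive")
    with np.errstate(invalid="ignore"):
        crit = (vel.vx / vel.eta_x) ** 2 + (vel.vy / vel.eta_y) ** 2
    mask = np.nan_to_num(crit, nan=0.0) > 1.0

    rows = []
    for start, stop in _runs(mask):
        if stop - start < params.min_saccade_samples:
            continue
        i1 = min(stop, len(vel.x) - 1)
        dx = vel.x[i1] - vel.x[start]
        dy = vel.y[i1] - vel.y[start]
        speed = np.sqrt(vel.vx[start:stop] ** 2 + vel.vy[start:stop] ** 2)
        rows.append(dict(
            event_type="saccade",
            onset_sample=int(round(vel.t[start] * vel.rate)),
            duration_ms=(stop - start) / vel.rate * 1000.0,
            aoi="none",
            amplitude=float(np.hypot(dx, dy)),
            peak_velocity=float(np.nanmax(speed)),
            prior_saccade_amplitude=np.nan,
            start_index=start,
            stop_index=stop,
        ))
    if not rows:
        out = empty_events()
        out["start_index"] = pd.Series(dtype=int)
        out["stop_index"] = pd.Series(dtype=int)
        return out
    return pd.DataFrame(rows)


def derive_fixations(saccades: pd.DataFrame, gaze: GazeStream) -> pd.DataFrame:
    """Fixations as the complement of saccades, split at gaze gaps.

    Intervals are expressed in gaze sample indices (``start_index`` /
    ``stop_index``, half-open) and trimmed at the stream edges; any gap
    inside an inter-saccade interval splits it into separate fixations.
    Onset is the first post-saccadic sample.
    """
    n = len(gaze)
    occupied = np.zeros(n, dtype=bool)
    for row in saccades.itertuples():
        occupied[int(row.start_index):int(row.stop_index)] = True
    occupied |= gaze.gap_mask

    rows = []
    for start, stop in _runs(~occupied):
        rows.append(dict(
            event_type="fixation",
            onset_sample=int(round(gaze.t[start] * gaze.rate)),
            duration_ms=(stop - start) / gaze.rate * 1000.0,
            aoi="none",
            amplitude=np.nan,
            peak_velocity=np.nan,
            prior_saccade_amplitude=np.nan,
            start_index=start,
            stop_index=stop,
        ))
    if not rows:
        out = empty_events()
        out["start_index"] = pd.Series(dtype=int)
        out["stop_index"] = pd.Series(dtype=int)
        return out
    return pd.DataFrame(rows)


def filter_fixations(fixations: pd.DataFrame, min_ms: float = 150.0,
                     max_ms: float = 2000.0) -> pd.DataFrame:
    """Retain fixations with ``min_ms <= duration <= max_ms``.

    Bounds are inclusive: the exclusion rule drops durations strictly below
    150 ms and strictly above 2000 ms.
    """
    keep = (fixations["duration_ms"] >= min_ms) & (fixations["duration_ms"] <= max_ms)
    return fixations[keep].reset_index(drop=True)


#: Tie-break priority for AOI majority votes: the Environment baseline wins
#: ties (conservative — biases against landmark effects), then LM-Abstract.
_AOI_PRIORITY = {label: i for i, label in enumerate(AOI_CONDITIONS)}


def assign_aoi(fixations: pd.DataFrame, gaze: GazeStream) -> pd.DataFrame:
    """Label each fixation with the majority AOI of its raw gaze samples.

    ``none`` samples are excluded from the vote; fixations with no labelled
    samples at all are dropped. Exact ties resolve by the fixed priority
    Environment > LM-Abstract > LM-Realistic.
    """
    keep_rows = []
    labels = []
    for i, row in enumerate(fixations.itertuples()):
        votes = gaze.aoi[int(row.start_index):int(row.stop_index)]
        votes = votes[votes != "none"]
        if len(votes) == 0:
            continue
        uniq, counts = np.unique(votes.astype(str), return_counts=True)
        top = counts.max()
        tied = [u for u, c in zip(uniq, counts) if c == top]
        labels.append(min(tied, key=lambda u: _AOI_PRIORITY[u]))
        keep_rows.append(i)
    out = fixations.iloc[keep_rows].copy().reset_index(drop=True)
    out["aoi"] = labels
    return out


def attach_prior_saccade(fixations: pd.DataFrame,
                         saccades: pd.DataFrame) -> pd.DataFrame:
    """Attach the amplitude of the immediately preceding saccade.

    Fixations with no preceding saccade keep a NaN marker; the deconvolution
    design later excludes them rather than imputing.
    """
    out = fixations.copy().reset_index(drop=True)
    if len(saccades) == 0 or len(out) == 0:
        out["prior_saccade_amplitude"] = np.nan
        return out
    s_on = saccades["onset_sample"].to_numpy()
    s_amp = saccades["amplitude"].to_numpy()
    order = np.argsort(s_on, kind="stable")
    s_on, s_amp = s_on[order], s_amp[order]
    idx = np.searchsorted(s_on, out["onset_sample"].to_numpy(), side="right") - 1
    prior = np.where(idx >= 0, s_amp[np.clip(idx, 0, None)], np.nan)
    out["prior_saccade_amplitude"] = prior
    return out


def detect_events(gaze: GazeStream,
                  params: DetectionParams | None = None) -> pd.DataFrame:
    """Full parse: saccades + filtered, AOI-labelled, prior-annotated fixations.

    ``gaze`` must already be synchronized to the EEG clock (and typically
    upsampled to the EEG rate) so onsets are EEG sample indices.
    """
    params = params or DetectionParams()
    vel = compute_velocity(gaze, params)
    saccades = detect_saccades(vel, params)
    fixations = derive_fixations(saccades, gaze)
    fixations = filter_fixations(fixations, params.min_fix_ms, params.max_fix_ms)
    fixations = assign_aoi(fixations, gaze)
    fixations = attach_prior_saccade(fixations, saccades)
    events = pd.concat([saccades, fixations], ignore_index=True)
    events = events.sort_values("onset_sample", kind="stable").reset_index(drop=True)
    return validate_events(events.drop(columns=["start_index", "stop_index"]))
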
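"""EEG–eye-tracker synchronization by bounded cross-correlation.

Mobile coregistration platforms commonly leave a constant offset of a few
hundred milliseconds between the EEG and gaze clocks. Following the
EOG-correlation approach, the offset is estimated by cross-correlating a
horizontal-eye signal carried in the EEG with the horizontal gaze position,
restricted to lags within ±10 s; the lag of the largest |Pearson r| is then
applied to the gaze timestamps. Because the polarity of an EEG-derived eye
component is arbitrary, |r| rather than signed r is maximised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import correlate

from .core import GazeStream

__all__ = ["LagEstimate", "estimate_lag", "apply_lag", "upsample_gaze",
           "gaze_on_grid"]


@dataclass
class LagEstimate:
    """Result of the cross-correlation lag search.

    ``lag_ms`` is signed: positive means the gaze stream lags the EEG (gaze
    content recorded at timestamp ``tau`` belongs to EEG time
    ``tau + lag``). ``peak_correlation`` keeps its sign; the search
    maximises its absolute value.
    """

    lag_ms: float
    peak_correlation: float
    lags_ms: np.ndarray
    correlation: np.ndarray


def _bridge_gaps(sig: np.ndarray) -> np.ndarray:
    """Linearly interpolate non-finite runs (correlation only, never stored)."""
    sig = np.asarray(sig, dtype=float)
    finite = np.isfinite(sig)
    if finite.all():
        return sig
    if not finite.any():
        raise ValueError("signal is entirely non-finite")
    idx = np.arange(len(sig))
    out = sig.copy()
    out[~finite] = np.interp(idx[~finite], idx[finite], sig[finite])
    return out


def estimate_lag(eye_channel: np.ndarray, gaze_x: np.ndarray, rate: float,
                 max_lag_ms: float = 10_000.0) -> LagEstimate:
    """Find the lag maximising |Pearson r| between two equally sampled signals.

    Both signals must share the sampling ``rate``; the correlation at every
    integer-sample lag within ``±max_lag_ms`` is computed with per-overlap
    mean centering. Ties in |r| resolve to the smallest |lag|.

    Raises on all-constant input (undefined correlation).
    """
    a = _bridge_gaps(np.asarray(eye_channel, dtype=float))
    b = _bridge_gaps(np.asarray(gaze_x, dtype=float))
    n = min(len(a), len(b))
    a, b = a[:n], b[:n]
    max_lag = int(round(max_lag_ms / 1000.0 * rate))
    if n < 2 * max_lag:
        raise ValueError(
            f"signals too short ({n} samples) for ±{max_lag_ms} ms lag search "
            f"at {rate} Hz; need at least {2 * max_lag}"
        )
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant signal: correlation undefined")

    # cross term for every lag via FFT; windowed moments via cumulative sums
    full = correlate(a, b, mode="full", method="fft")  # index n-1+L -> sum a[i+L] b[i]
    lags = np.arange(-max_lag, max_lag + 1)
    cross = full[(n - 1) + lags]

    ca = np.concatenate([[0.0], np.cumsum(a)])
    ca2 = np.concatenate([[0.0], np.cumsum(a * a)])
    cb = np.concatenate([[0.0], np.cumsum(b)])
    cb2 = np.concatenate([[0.0], np.cumsum(b * b)])

    L = lags
    m = (n - np.abs(L)).astype(float)         # overlap length per lag
    a_lo = np.maximum(L, 0)
    a_hi = n + np.minimum(L, 0)
    b_lo = np.maximum(-L, 0)
    b_hi = n - np.maximum(L, 0)
    sa = ca[a_hi] - ca[a_lo]
    sa2 = ca2[a_hi] - ca2[a_lo]
    sb = cb[b_hi] - cb[b_lo]
    sb2 = cb2[b_hi] - cb2[b_lo]

    cov = cross - sa * sb / m
    var_a = np.maximum(sa2 - sa * sa / m, 0.0)
    var_b = np.maximum(sb2 - sb * sb / m, 0.0)
    denom = np.sqrt(var_a * var_b)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, cov / denom, 0.0)
    r = np.clip(r, -1.0, 1.0)

    best = np.abs(r) >= np.abs(r).max() - 1e-12
    cand = np.flatnonzero(best)
    pick = cand[np.argmin(np.abs(lags[cand]))]   # tie-break: smallest |lag|
    return LagEstimate(
        lag_ms=lags[pick] / rate * 1000.0,
        peak_correlation=float(r[pick]),
        lags_ms=lags / rate * 1000.0,
        correlation=r,
    )


def apply_lag(gaze: GazeStream, lag_ms: float) -> GazeStream:
    """Shift gaze timestamps by ``lag_ms`` onto the EEG clock.

    A positive lag (gaze lagging EEG) moves gaze timestamps forward; AOI
    labels travel with their samples.
    """
    if abs(lag_ms) > 10_000:
        raise ValueError(f"|lag_ms| must be <= 10000, got {lag_ms}")
    out = gaze.copy()
    out.t = out.t + lag_ms / 1000.0
    return out


def upsample_gaze(gaze: GazeStream, target_rate: float) -> GazeStream:
    """Upsample gaze to ``target_rate`` (typically the EEG rate).

    Positions are linearly interpolated, AOI labels carried by nearest
    neighbour, and gaps (non-finite positions) remain gaps: a target sample
    whose bracketing source samples include a gap stays non-finite.
    """
    if target_rate < gaze.rate:
        raise ValueError(
            f"target rate {target_rate} Hz below source rate {gaze.rate} Hz; "
            "gaze is only ever upsampled"
        )
    if target_rate == gaze.rate:
        return gaze.copy()
    t = gaze.t
    # the stream covers [t0, t0 + n/rate); keep that span at the new rate
    span = (t[-1] - t[0]) + 1.0 / gaze.rate
    n_out = int(np.floor(span * target_rate + 1e-9))
    tt = t[0] + np.arange(n_out) / target_rate

    right = np.clip(np.searchsorted(t, tt, side="right"), 1, len(t) - 1)
    left = right - 1
    w = (tt - t[left]) / (t[right] - t[left])
    w = np.clip(w, 0.0, 1.0)
    x = gaze.x[left] * (1 - w) + gaze.x[right] * w   # NaN endpoints propagate
    y = gaze.y[left] * (1 - w) + gaze.y[right] * w
    nearest = np.where(w < 0.5, left, right)
    aoi = gaze.aoi[nearest]
    return GazeStream(tt, x, y, aoi, rate=target_rate, unit=gaze.unit)


def gaze_on_grid(gaze: GazeStream, rate: float, n_samples: int,
                 start_time: float = 0.0) -> np.ndarray:
    """Gaze x resampled onto an EEG sample grid (same clock as ``gaze.t``).

    Samples outside the gaze extent are NaN; used to feed
    :func:`estimate_lag` with both signals on the EEG grid.
    """
    times = start_time + np.arange(n_samples) / rate
    x = _bridge_gaps(gaze.x) if np.isfinite(gaze.x).any() else gaze.x
    out = np.interp(times, gaze.t, x, left=np.nan, right=np.nan)
    return out
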
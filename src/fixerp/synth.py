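"""Synthetic coregistered EEG + gaze cohorts with known ground truth.

The generator emulates the structure of a mobile map-navigation session:
an alternating fixation/saccade scanpath over three areas of interest
(Environment, LM-Abstract, LM-Realistic), fixation-locked evoked responses
(lambda/P1 scaled by the preceding saccade's amplitude, N1, P200 with
AOI-dependent amplitude offsets, a late positive plateau), a saccadic spike
potential locked to saccade onsets, gait-step artifacts at walking cadence,
1/f ("pink") plus white sensor noise, a horizontal-eye nuisance channel
proportional to gaze x, and a constant temporal offset between the EEG and
eye-tracker clocks.

Everything injected is retrievable from the returned :class:`GroundTruth`,
so every downstream stage (synchronization, event detection, deconvolution,
peak extraction, statistics) can be tested against known truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    AOI_CONDITIONS,
    CLUSTERS,
    DEFAULT_MONTAGE,
    EVENT_COLUMNS,
    ContinuousEEG,
    GazeStream,
    validate_events,
)

__all__ = [
    "ScanpathParams",
    "NoiseParams",
    "Component",
    "KernelSpec",
    "GroundTruth",
    "SubjectRecording",
    "CohortConfig",
    "default_kernels",
    "bandpassed_fixation_response",
    "sample_scanpath",
    "build_trajectory",
    "render_eeg",
    "render_gaze",
    "generate_subject",
    "generate_cohort",
]

#: Name of the horizontal-eye nuisance channel appended to rendered EEG.
EYE_CHANNEL = "EyeH"


# --------------------------------------------------------------------------
# Parameter containers
# --------------------------------------------------------------------------

@dataclass
class ScanpathParams:
    """Distributional parameters of the simulated scanpath.

    Fixation durations are lognormal with median 300 ms and log-SD 0.5,
    truncated to [80, 2600] ms; saccade amplitudes gamma(shape 2, scale 2.5)
    degrees; per-fixation AOI multinomial with Environment-heavy weights
    matching the epoch-count ratios typical of map-navigation sessions; gait steps at 1.8 Hz cadence
    with 5 % timing jitter.
    """

    fix_median_s: float = 0.300
    fix_log_sd: float = 0.5
    fix_trunc_s: tuple[float, float] = (0.080, 2.600)
    sacc_amp_shape: float = 2.0
    sacc_amp_scale: float = 2.5
    p_env: float = 0.78
    p_abs: float = 0.11
    p_real: float = 0.11
    step_cadence_hz: float = 1.8
    step_jitter: float = 0.05
    position_bound_deg: float = 20.0

    @property
    def aoi_probs(self) -> tuple[float, float, float]:
        return (self.p_env, self.p_abs, self.p_real)


@dataclass
class NoiseParams:
    """Sensor-noise levels (µV per channel)."""

    pink_sd: float = 3.0
    white_sd: float = 1.0
    gaze_noise_deg: float = 0.05


@dataclass
class Component:
    """One evoked-response kernel.

    ``shape``: ``gauss`` (Gaussian bump, ``width_ms`` = SD), ``dgauss``
    (biphasic derivative-of-Gaussian, peak magnitude = ``amplitude_uv``) or
    ``plateau`` (raised-cosine plateau starting at ``latency_ms`` lasting
    ``width_ms``). ``topography`` holds one weight per montage channel.
    """

    name: str
    shape: str
    latency_ms: float
    width_ms: float
    amplitude_uv: float
    topography: np.ndarray

    def waveform(self, lags_ms: np.ndarray, gain: float = 1.0,
                 amp_offset: float = 0.0) -> np.ndarray:
        """Kernel value at each lag (ms), scalar over channels."""
        t = np.asarray(lags_ms, dtype=float)
        amp = gain * self.amplitude_uv + amp_offset
        if self.shape == "gauss":
            z = (t - self.latency_ms) / self.width_ms
            return amp * np.exp(-0.5 * z * z) * (np.abs(z) <= 5.0)
        if self.shape == "dgauss":
            z = (t - self.latency_ms) / self.width_ms
            return amp * (-z) * np.exp(0.5 - 0.5 * z * z) * (np.abs(z) <= 5.0)
        if self.shape == "plateau":
            ramp = 50.0  # ms raised-cosine edges
            t0, t1 = self.latency_ms, self.latency_ms + self.width_ms
            w = np.zeros_like(t)
            rising = (t >= t0 - ramp) & (t < t0)
            falling = (t > t1) & (t <= t1 + ramp)
            flat = (t >= t0) & (t <= t1)
            w[rising] = 0.5 * (1 - np.cos(np.pi * (t[rising] - t0 + ramp) / ramp))
            w[falling] = 0.5 * (1 + np.cos(np.pi * (t[falling] - t1) / ramp))
            w[flat] = 1.0
            return amp * w
        raise ValueError(f"unknown kernel shape {self.shape!r}")

    @property
    def support_ms(self) -> tuple[float, float]:
        if self.shape == "plateau":
            return (self.latency_ms - 50.0, self.latency_ms + self.width_ms + 50.0)
        return (self.latency_ms - 5 * self.width_ms, self.latency_ms + 5 * self.width_ms)


@dataclass
class KernelSpec:
    """The full set of ground-truth kernels for one subject.

    Fixation-locked: P1 (lambda, amplitude multiplied by ``gain(a)`` of the
    prior saccade amplitude ``a``), N1, P200 (per-AOI amplitude offsets
    ``delta_abstract``/``delta_realistic``), LPC. Saccade-locked: spike
    potential. Step-locked: gait artifact.
    """

    montage: tuple[str, ...]
    components: dict[str, Component]
    gain_coef: float = 0.25           # lambda gain g(a) = 1 + gain_coef*ln(1+a)
    delta_abstract: float = -0.02     # µV, P200 offset vs Environment
    delta_realistic: float = 0.28

    def gain(self, amplitude_deg: float | np.ndarray) -> float | np.ndarray:
        """Monotone lambda gain as a function of prior saccade amplitude."""
        return 1.0 + self.gain_coef * np.log1p(np.maximum(amplitude_deg, 0.0))

    def p200_offset(self, aoi: str) -> float:
        return {"Environment": 0.0, "LM-Abstract": self.delta_abstract,
                "LM-Realistic": self.delta_realistic}[aoi]

    def _stack(self, names: list[str], lags_ms: np.ndarray,
               gains: dict[str, float], offsets: dict[str, float]) -> np.ndarray:
        out = np.zeros((len(self.montage), len(lags_ms)))
        for name in names:
            comp = self.components[name]
            w = comp.waveform(lags_ms, gain=gains.get(name, 1.0),
                              amp_offset=offsets.get(name, 0.0))
            out += np.outer(comp.topography, w)
        return out

    def fixation_response(self, lags_ms: np.ndarray, aoi: str = "Environment",
                          prior_amplitude: float | None = None) -> np.ndarray:
        """Noise-free fixation-locked response, channels x lags (µV)."""
        gain = 1.0 if prior_amplitude is None or not np.isfinite(prior_amplitude) \
            else float(self.gain(prior_amplitude))
        return self._stack(
            ["P1", "N1", "P200", "LPC"], lags_ms,
            gains={"P1": gain}, offsets={"P200": self.p200_offset(aoi)},
        )

    def saccade_response(self, lags_ms: np.ndarray) -> np.ndarray:
        return self._stack(["sacc_spike"], lags_ms, {}, {})

    def step_response(self, lags_ms: np.ndarray) -> np.ndarray:
        return self._stack(["step"], lags_ms, {}, {})


def _topo(montage: tuple[str, ...], weights: dict[str, float],
          default: float = 0.0) -> np.ndarray:
    return np.array([weights.get(ch, default) for ch in montage])


def _avg_ref_topo(montage: tuple[str, ...], weights: dict[str, float],
                  anchor_cluster: str | None = None) -> np.ndarray:
    """Topography in the average-reference frame.

    Weights are centered to zero mean across the montage (what an
    average-referenced recording of any dipolar source looks like) and,
    when ``anchor_cluster`` is given, rescaled so the mean weight over that
    cluster equals 1 — making the component's ``amplitude_uv`` (and any
    condition offset) land one-to-one on that cluster's ERP.
    """
    w = _topo(montage, weights)
    w = w - w.mean()
    if anchor_cluster is not None:
        members = [montage.index(ch) for ch in CLUSTERS[anchor_cluster]]
        scale = w[members].mean()
        if abs(scale) < 1e-6:
            raise ValueError(f"near-zero {anchor_cluster} mean after centering")
        w = w / scale
    else:
        w = w / np.abs(w).max()
    return w


def default_kernels(montage: tuple[str, ...] = DEFAULT_MONTAGE,
                    delta_abstract: float = -0.02,
                    delta_realistic: float = 0.28) -> KernelSpec:
    """Default kernel set at the magnitudes typical of walking-navigation FRPs.

    The parietal P200 baseline amplitude and the condition offsets default
    to 1.16 µV and (-0.02, +0.28) µV so pipeline output is on the same scale
    as published mobile-navigation FRP peak tables; the lambda grows with
    the prior saccade amplitude through ``gain``.
    """
    for cluster, members in CLUSTERS.items():
        missing = set(members) - set(montage)
        if missing:
            raise ValueError(f"montage missing {cluster} electrodes {sorted(missing)}")
    occ = {"Oz": 1.0, "O1": 0.95, "O2": 0.95}
    par = {"Pz": 1.0, "P1": 0.92, "P2": 0.92, "POz": 0.97, "CPz": 0.88}
    fro = {"Fz": 1.0, "F1": 0.92, "F2": 0.92, "AFz": 0.95, "FCz": 0.9}
    # Topographies live in the average-reference frame (zero mean over the
    # montage) and are anchored so each component's amplitude_uv lands 1:1
    # on its target cluster ERP; see _avg_ref_topo.
    comps = {
        "P1": Component("P1", "gauss", 90.0, 16.0, 4.30, _avg_ref_topo(montage, {
            **occ, **{k: 0.45 * v for k, v in par.items()},
            **{k: -0.15 * v for k, v in fro.items()}, "Cz": 0.25, "C3": 0.15, "C4": 0.15,
        }, "occipital")),
        "N1": Component("N1", "gauss", 157.0, 18.0, -2.30, _avg_ref_topo(montage, {
            **occ, **{k: 0.30 * v for k, v in par.items()},
            **{k: -0.30 * v for k, v in fro.items()}, "Cz": 0.10,
        }, "occipital")),
        "P200": Component("P200", "gauss", 186.0, 25.0, 1.16, _avg_ref_topo(montage, {
            **par, **{k: 0.30 * v for k, v in fro.items()},
            **{k: 0.30 * v for k, v in occ.items()}, "Cz": 0.55, "C3": 0.3, "C4": 0.3,
        }, "parietal")),
        "LPC": Component("LPC", "plateau", 500.0, 300.0, -0.28, _avg_ref_topo(montage, {
            **par, **{k: 0.20 * v for k, v in fro.items()},
            **{k: 0.30 * v for k, v in occ.items()}, "Cz": 0.4,
        }, "parietal")),
        "sacc_spike": Component("sacc_spike", "dgauss", 15.0, 8.0, -8.0, _avg_ref_topo(montage, {
            **occ, **{k: 0.60 * v for k, v in par.items()},
            **{k: 0.20 * v for k, v in fro.items()}, "Cz": 0.3,
        }, "occipital")),
        "step": Component("step", "gauss", 100.0, 60.0, 5.0, _avg_ref_topo(montage, {
            "Cz": 1.0, "C3": 0.9, "C4": 0.9,
            **{k: 0.8 * v for k, v in fro.items()},
            **{k: 0.7 * v for k, v in par.items()},
            **{k: 0.5 * v for k, v in occ.items()},
        })),
    }
    return KernelSpec(tuple(montage), comps,
                      delta_abstract=delta_abstract, delta_realistic=delta_realistic)


# --------------------------------------------------------------------------
# Scanpath
# --------------------------------------------------------------------------

def sample_scanpath(duration_s: float, params: ScanpathParams | None = None,
                    rng: np.random.Generator | None = None,
                    rate: float = 500.0) -> pd.DataFrame:
    """Sample a ground-truth event table tiling ``duration_s`` seconds.

    Fixations and saccades alternate (fixation first); gait-step events are
    interleaved at walking cadence. Onsets are sample indices at ``rate``.
    The returned frame carries the canonical event columns plus ground-truth
    gaze coordinates ``x_pos``/``y_pos`` (fixation position; saccade rows
    store the movement start, ``x_end``/``y_end`` the landing position).
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    params = params or ScanpathParams()
    rng = rng or np.random.default_rng()
    probs = np.array(params.aoi_probs, dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError(f"AOI probabilities must sum to 1, got {probs.sum()}")

    bound = params.position_bound_deg
    mu = np.log(params.fix_median_s)
    rows: list[dict] = []
    t = 0.0
    x, y = rng.uniform(-bound / 2, bound / 2, size=2)
    while True:
        # fixation
        dur = float(np.exp(rng.normal(mu, params.fix_log_sd)))
        dur = float(np.clip(dur, *params.fix_trunc_s))
        if t + dur > duration_s:
            break
        aoi = AOI_CONDITIONS[rng.choice(3, p=probs)]
        rows.append(dict(event_type="fixation", onset_s=t, duration_s=dur,
                         aoi=aoi, amplitude=np.nan, x_pos=x, y_pos=y,
                         x_end=x, y_end=y))
        t += dur
        # saccade
        amp = float(rng.gamma(params.sacc_amp_shape, params.sacc_amp_scale))
        amp = max(amp, 0.1)
        sdur = (21.0 + 2.2 * amp) / 1000.0
        if t + sdur > duration_s:
            break
        theta = rng.uniform(0, 2 * np.pi)
        nx, ny = x + amp * np.cos(theta), y + amp * np.sin(theta)
        if abs(nx) > bound or abs(ny) > bound:  # redirect toward center
            theta = np.arctan2(-y, -x) + rng.normal(0, 0.3)
            nx, ny = x + amp * np.cos(theta), y + amp * np.sin(theta)
        rows.append(dict(event_type="saccade", onset_s=t, duration_s=sdur,
                         aoi="none", amplitude=amp, x_pos=x, y_pos=y,
                         x_end=nx, y_end=ny))
        t += sdur
        x, y = nx, ny

    # gait steps at cadence with jitter
    period = 1.0 / params.step_cadence_hz
    st = period
    while st < duration_s:
        rows.append(dict(event_type="step", onset_s=st + rng.normal(0, params.step_jitter * period),
                         duration_s=0.0, aoi="none", amplitude=np.nan,
                         x_pos=np.nan, y_pos=np.nan, x_end=np.nan, y_end=np.nan))
        st += period

    df = pd.DataFrame(rows)
    df = df[df["onset_s"] >= 0].sort_values("onset_s", kind="stable").reset_index(drop=True)

    # prior saccade amplitude for each fixation
    prior = np.full(len(df), np.nan)
    last_amp = np.nan
    for i, row in enumerate(df.itertuples()):
        if row.event_type == "saccade":
            last_amp = row.amplitude
        elif row.event_type == "fixation":
            prior[i] = last_amp
            last_amp = np.nan

    sdur = df["duration_s"].to_numpy()
    amp = df["amplitude"].to_numpy()
    peak_v = np.where(df["event_type"] == "saccade",
                      amp * np.pi / (2 * np.maximum(sdur, 1e-6)), np.nan)
    out = pd.DataFrame({
        "event_type": df["event_type"],
        "onset_sample": np.round(df["onset_s"].to_numpy() * rate).astype(int),
        "duration_ms": sdur * 1000.0,
        "aoi": df["aoi"],
        "amplitude": amp,
        "peak_velocity": peak_v,
        "prior_saccade_amplitude": prior,
        "x_pos": df["x_pos"], "y_pos": df["y_pos"],
        "x_end": df["x_end"], "y_end": df["y_end"],
    })
    return validate_events(out)


def build_trajectory(events: pd.DataFrame, rate: float = 500.0):
    """Return ``f(times_s) -> (x, y)`` evaluating the scanpath trajectory.

    Piecewise-constant during fixations, raised-cosine ramps during
    saccades; constant extrapolation outside the tiled range.
    """
    ev = events[events["event_type"].isin(["fixation", "saccade"])]
    onsets = ev["onset_sample"].to_numpy() / rate
    durs = ev["duration_ms"].to_numpy() / 1000.0
    x0 = ev["x_pos"].to_numpy(float)
    y0 = ev["y_pos"].to_numpy(float)
    x1 = ev["x_end"].to_numpy(float)
    y1 = ev["y_end"].to_numpy(float)
    is_sacc = (ev["event_type"] == "saccade").to_numpy()

    def f(times_s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        t = np.asarray(times_s, dtype=float)
        idx = np.clip(np.searchsorted(onsets, t, side="right") - 1, 0, len(onsets) - 1)
        frac = np.clip((t - onsets[idx]) / np.maximum(durs[idx], 1e-9), 0.0, 1.0)
        ramp = np.where(is_sacc[idx], 0.5 * (1 - np.cos(np.pi * frac)), 0.0)
        return (x0[idx] + ramp * (x1[idx] - x0[idx]),
                y0[idx] + ramp * (y1[idx] - y0[idx]))

    return f


# --------------------------------------------------------------------------
# Rendering
# --------------------------------------------------------------------------

def _pink_noise(n: int, sd: float, rng: np.random.Generator) -> np.ndarray:
    """1/f-power ("pink") noise of length ``n`` normalised to SD ``sd``."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    shaping = np.ones_like(freqs)
    shaping[1:] = 1.0 / np.sqrt(freqs[1:])
    shaping[0] = 0.0
    shaped = np.fft.irfft(spec * shaping, n=n)
    s = shaped.std()
    return shaped * (sd / s) if s > 0 else shaped


def render_eeg(events: pd.DataFrame, kernels: KernelSpec,
               montage: tuple[str, ...] | None = None,
               noise: NoiseParams | None = None,
               rate: float = 500.0,
               rng: np.random.Generator | None = None,
               duration_s: float | None = None) -> ContinuousEEG:
    """Render continuous EEG as a superposition of event-locked kernels.

    Pass ``noise=None`` for a noise-free rendering (exact superposition of
    kernel placements — the oracle used by the deconvolution tests).
    """
    montage = tuple(montage or kernels.montage)
    missing = {ch for m in CLUSTERS.values() for ch in m} - set(montage)
    if missing:
        raise ValueError(f"montage missing cluster electrodes {sorted(missing)}")
    if tuple(kernels.montage) != montage:
        raise ValueError("kernel topographies defined on a different montage")
    rng = rng or np.random.default_rng()

    if duration_s is None:
        last = (events["onset_sample"].max() / rate) + events["duration_ms"].max() / 1000.0
        duration_s = last + 1.5
    n = int(round(duration_s * rate))
    data = np.zeros((len(montage), n))

    supports = {}
    for names, resp in (
        (("P1", "N1", "P200", "LPC"), "fix"),
        (("sacc_spike",), "sacc"),
        (("step",), "step"),
    ):
        lo = min(kernels.components[c].support_ms[0] for c in names)
        hi = max(kernels.components[c].support_ms[1] for c in names)
        lag0 = int(np.floor(lo / 1000.0 * rate))
        lag1 = int(np.ceil(hi / 1000.0 * rate))
        lags_ms = np.arange(lag0, lag1 + 1) / rate * 1000.0
        supports[resp] = (lag0, lags_ms)

    for row in events.itertuples():
        if row.event_type == "fixation":
            lag0, lags_ms = supports["fix"]
            resp = kernels.fixation_response(
                lags_ms, aoi=row.aoi, prior_amplitude=row.prior_saccade_amplitude)
        elif row.event_type == "saccade":
            lag0, lags_ms = supports["sacc"]
            resp = kernels.saccade_response(lags_ms)
        else:
            lag0, lags_ms = supports["step"]
            resp = kernels.step_response(lags_ms)
        a = int(row.onset_sample) + lag0
        b = a + resp.shape[1]
        ka, kb = max(0, -a), resp.shape[1] - max(0, b - n)
        if kb <= ka:
            continue
        data[:, max(a, 0):min(b, n)] += resp[:, ka:kb]

    if noise is not None:
        for ch in range(len(montage)):
            data[ch] += _pink_noise(n, noise.pink_sd, rng)
        if noise.white_sd > 0:
            data += rng.normal(0, noise.white_sd, size=data.shape)

    return ContinuousEEG(data, rate, montage, reference="FCz")


def render_gaze(events: pd.DataFrame, offset_ms: float,
                gaze_rate: float = 200.0,
                rng: np.random.Generator | None = None,
                noise: NoiseParams | None = None,
                eeg: ContinuousEEG | None = None,
                nuisance_gain_uv_per_deg: float = 20.0,
                nuisance_sign: int = 1,
                eeg_rate: float = 500.0):
    """Render the gaze stream (and optionally the EEG eye nuisance channel).

    Gaze timestamps run on the eye tracker's own clock, which is *behind*
    the EEG clock by ``offset_ms`` (positive offset = gaze lags EEG): the
    sample recorded at gaze time ``tau`` shows what happened at EEG time
    ``tau + offset_ms/1000``.

    If ``eeg`` is given, a horizontal-eye channel ``EyeH`` proportional to
    the true gaze x on the *EEG* clock is appended and the pair
    ``(gaze, eeg_with_nuisance)`` is returned; otherwise just the gaze.
    """
    if abs(offset_ms) > 10_000:
        raise ValueError(f"|offset_ms| must be <= 10000, got {offset_ms}")
    rng = rng or np.random.default_rng()
    traj = build_trajectory(events, rate=eeg_rate)

    last = (events["onset_sample"].max() / eeg_rate) + events["duration_ms"].max() / 1000.0
    t_end = last - offset_ms / 1000.0
    tg = np.arange(0.0, max(t_end, 1.0 / gaze_rate), 1.0 / gaze_rate)
    true_t = tg + offset_ms / 1000.0
    x, y = traj(true_t)
    if noise is not None and noise.gaze_noise_deg > 0:
        x = x + rng.normal(0, noise.gaze_noise_deg, size=x.shape)
        y = y + rng.normal(0, noise.gaze_noise_deg, size=y.shape)

    aoi = _aoi_at_times(events, true_t, eeg_rate)
    gaze = GazeStream(tg, x, y, aoi, rate=gaze_rate)

    if eeg is None:
        return gaze
    times = eeg.start_time + np.arange(eeg.n_samples) / eeg.rate
    ex, _ = traj(times)
    nuis = nuisance_sign * nuisance_gain_uv_per_deg * (ex - ex.mean())
    if noise is not None:
        nuis = nuis + _pink_noise(eeg.n_samples, noise.pink_sd, rng)
    data = np.vstack([eeg.data, nuis])
    out = ContinuousEEG(data, eeg.rate, eeg.channel_names + (EYE_CHANNEL,),
                        reference=eeg.reference, start_time=eeg.start_time)
    return gaze, out


def _aoi_at_times(events: pd.DataFrame, times_s: np.ndarray, rate: float) -> np.ndarray:
    ev = events[events["event_type"] == "fixation"]
    onsets = ev["onset_sample"].to_numpy() / rate
    ends = onsets + ev["duration_ms"].to_numpy() / 1000.0
    labels = ev["aoi"].to_numpy()
    aoi = np.full(len(times_s), "none", dtype=object)
    idx = np.searchsorted(onsets, times_s, side="right") - 1
    valid = idx >= 0
    inside = np.zeros(len(times_s), dtype=bool)
    inside[valid] = times_s[valid] < ends[idx[valid]]
    aoi[inside] = labels[idx[inside]]
    return aoi


def bandpassed_fixation_response(kernels: KernelSpec, lags_ms: np.ndarray,
                                 rate: float, aoi: str = "Environment",
                                 prior_amplitude: float | None = None,
                                 low_hz: float = 1.0, high_hz: float = 30.0,
                                 pad_s: float = 30.0) -> np.ndarray:
    """Ground-truth fixation response as it appears after band-pass filtering.

    Band-pass filtering is linear and time-invariant, so the filtered EEG is
    the superposition of *filtered* kernels: estimates obtained from
    filtered data must be compared against the kernel passed through the
    identical zero-phase FIR. The kernel is zero-padded generously (the
    high-pass transition implies an impulse response of tens of seconds)
    before filtering and cropped back to ``lags_ms``.
    """
    import mne

    pad = int(pad_s * rate)
    step = 1000.0 / rate
    ext = np.arange(lags_ms[0] - pad * step, lags_ms[-1] + pad * step + step / 2,
                    step)
    vals = kernels.fixation_response(ext, aoi, prior_amplitude)
    filt = mne.filter.filter_data(
        vals, rate, low_hz, high_hz,
        l_trans_bandwidth=0.25 * low_hz, h_trans_bandwidth=0.25 * high_hz,
        fir_design="firwin", fir_window="hamming", phase="zero",
        verbose="error")
    return filt[:, pad:pad + len(lags_ms)]


# --------------------------------------------------------------------------
# Cohorts
# --------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Everything injected into one simulated subject."""

    events: pd.DataFrame
    kernels: KernelSpec
    offset_ms: float
    noise: NoiseParams | None
    aoi_probs: tuple[float, float, float]
    gender: str
    seed: int


@dataclass
class SubjectRecording:
    subject: str
    eeg: ContinuousEEG
    gaze: GazeStream
    truth: GroundTruth
    meta: dict


@dataclass
class CohortConfig:
    """Study-condition defaults for a simulated cohort.

    ``duration_s`` of 210 s yields roughly 500 retained fixations per
    subject at the default scanpath statistics; per-subject EEG–gaze
    offsets are drawn uniformly from the 134–1776 ms range observed for
    mobile co-registration setups.
    """

    duration_s: float = 210.0
    eeg_rate: float = 500.0
    gaze_rate: float = 200.0
    offset_range_ms: tuple[float, float] = (134.0, 1776.0)
    scanpath: ScanpathParams = field(default_factory=ScanpathParams)
    noise: NoiseParams | None = field(default_factory=NoiseParams)
    delta_abstract: float = -0.02
    delta_realistic: float = 0.28
    nuisance_gain_uv_per_deg: float = 20.0
    montage: tuple[str, ...] = DEFAULT_MONTAGE


def generate_subject(subject: str, config: CohortConfig, seed: int,
                     gender: str = "female",
                     offset_ms: float | None = None) -> SubjectRecording:
    """Simulate one subject's coregistered session."""
    rng = np.random.default_rng(seed)
    if offset_ms is None:
        offset_ms = float(rng.uniform(*config.offset_range_ms))
    events = sample_scanpath(config.duration_s, config.scanpath, rng,
                             rate=config.eeg_rate)
    kernels = default_kernels(config.montage,
                              delta_abstract=config.delta_abstract,
                              delta_realistic=config.delta_realistic)
    eeg = render_eeg(events, kernels, config.montage, config.noise,
                     config.eeg_rate, rng)
    gaze, eeg = render_gaze(events, offset_ms, config.gaze_rate, rng,
                            noise=config.noise, eeg=eeg,
                            nuisance_gain_uv_per_deg=config.nuisance_gain_uv_per_deg,
                            eeg_rate=config.eeg_rate)
    truth = GroundTruth(events, kernels, offset_ms, config.noise,
                        config.scanpath.aoi_probs, gender, seed)
    meta = {"subject": subject, "gender": gender, "seed": seed,
            "offset_ms": offset_ms}
    return SubjectRecording(subject, eeg, gaze, truth, meta)


def generate_cohort(n_subjects: int, config: CohortConfig | None = None,
                    seed: int = 0) -> list[SubjectRecording]:
    """Simulate a gender-alternating cohort with independent subject seeds."""
    if n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    config = config or CohortConfig()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_subjects)
    out = []
    for i, child in enumerate(children):
        sub_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        gender = "female" if i % 2 == 0 else "male"
        out.append(generate_subject(f"sub-{i + 1:02d}", config, sub_seed, gender))
    return out
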
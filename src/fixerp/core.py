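"""Shared data types, readers/writers, and basic EEG signal conditioning.

The central containers are deliberately small:

* :class:`ContinuousEEG` — channels x samples array in microvolts with a
  sampling rate and channel labels (10 % system names).
* :class:`GazeStream` — timestamped gaze positions with a per-sample
  area-of-interest (AOI) label.
* Event tables are plain :class:`pandas.DataFrame` objects with the columns
  in :data:`EVENT_COLUMNS`; :func:`validate_events` enforces the contract.

On-disk formats are the field's standards: BrainVision (``.vhdr/.vmrk/.eeg``,
multiplexed IEEE float32) and EDF for EEG, BIDS-events-like TSV for event
tables, and CSV/TSV for gaze. Reading of EEG formats is delegated to MNE;
the writers are implemented here.
"""

from __future__ import annotations

import configparser
import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AOI_LABELS",
    "AOI_CONDITIONS",
    "CLUSTERS",
    "DEFAULT_MONTAGE",
    "EVENT_COLUMNS",
    "ContinuousEEG",
    "GazeStream",
    "FormatError",
    "validate_events",
    "read_eeg",
    "write_eeg",
    "read_gaze",
    "write_gaze",
    "read_events",
    "write_events",
    "bandpass",
    "resample",
    "rereference_average",
]

#: Closed set of per-sample gaze labels. ``none`` marks unlabelled samples
#: (saccades, gaps); the other three are the experimental conditions.
AOI_LABELS = ("Environment", "LM-Abstract", "LM-Realistic", "none")

#: The three analysable conditions (``none`` excluded).
AOI_CONDITIONS = ("Environment", "LM-Abstract", "LM-Realistic")

#: Electrode clusters used for regional ERPs.
CLUSTERS: dict[str, tuple[str, ...]] = {
    "occipital": ("Oz", "O1", "O2"),
    "parietal": ("Pz", "P1", "P2", "POz", "CPz"),
    "frontal": ("Fz", "F1", "F2", "AFz", "FCz"),
}

#: Default 16-channel montage covering every cluster electrode.
DEFAULT_MONTAGE = (
    "Oz", "O1", "O2",
    "Pz", "P1", "P2", "POz", "CPz",
    "Fz", "F1", "F2", "AFz", "FCz",
    "Cz", "C3", "C4",
)

#: Canonical event-table columns. ``onset_sample`` indexes the EEG timeline
#: (0-based, half-open intervals ``[onset, onset + duration)``).
EVENT_COLUMNS = (
    "event_type",           # saccade | fixation | step
    "onset_sample",
    "duration_ms",
    "aoi",                  # fixations only, else "none"
    "amplitude",            # saccades: endpoint displacement, degrees
    "peak_velocity",        # saccades: deg/s
    "prior_saccade_amplitude",  # fixations: degrees; NaN = missing
)

EVENT_TYPES = ("saccade", "fixation", "step")


class FormatError(ValueError):
    """A file does not conform to its declared on-disk format."""


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass
class ContinuousEEG:
    """Continuous multichannel EEG in microvolts.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    rate : float
        Sampling rate in samples/second.
    channel_names : tuple of str
        Unique ordered channel labels.
    reference : str
        Reference label (e.g. ``"FCz"``) or ``"average"``.
    start_time : float
        Time of the first sample in seconds.
    """

    data: np.ndarray
    rate: float
    channel_names: tuple[str, ...]
    reference: str = "FCz"
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channel_names = tuple(self.channel_names)
        if self.rate <= 0:
            raise ValueError(f"rate must be positive, got {self.rate}")
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} data rows"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("EEG data contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.rate

    def channel(self, name: str) -> np.ndarray:
        """Return one channel's samples by label."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"no channel named {name!r}") from None
        return self.data[idx]

    def copy(self) -> "ContinuousEEG":
        return replace(self, data=self.data.copy())


@dataclass
class GazeStream:
    """Timestamped gaze positions with per-sample AOI labels.

    Gaps (blinks, tracking loss) are explicit: non-finite ``x``/``y`` with
    ``aoi == "none"``. Timestamps are strictly increasing seconds.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    aoi: np.ndarray
    rate: float
    unit: str = "deg"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.aoi = np.asarray(self.aoi, dtype=object)
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.aoi) == n):
            raise ValueError("t, x, y, aoi must have equal length")
        if n >= 2 and not np.all(np.diff(self.t) > 0):
            raise ValueError("gaze timestamps must be strictly increasing")
        bad = set(self.aoi) - set(AOI_LABELS)
        if bad:
            raise ValueError(
                f"unknown AOI labels {sorted(bad)}; allowed: {list(AOI_LABELS)}"
            )
        if self.rate <= 0:
            raise ValueError(f"rate must be positive, got {self.rate}")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def gap_mask(self) -> np.ndarray:
        """Boolean mask of gap samples (non-finite position)."""
        return ~(np.isfinite(self.x) & np.isfinite(self.y))

    def copy(self) -> "GazeStream":
        return GazeStream(
            self.t.copy(), self.x.copy(), self.y.copy(),
            self.aoi.copy(), self.rate, self.unit,
        )


def validate_events(events: pd.DataFrame) -> pd.DataFrame:
    """Validate an event table against the package contract.

    Checks column presence, known event types, non-decreasing onsets and
    non-negative durations. Returns the (unmodified) frame for chaining.
    """
    missing = set(EVENT_COLUMNS) - set(events.columns)
    if missing:
        raise ValueError(f"event table missing columns {sorted(missing)}")
    bad = set(events["event_type"]) - set(EVENT_TYPES)
    if bad:
        raise ValueError(f"unknown event types {sorted(bad)}")
    onsets = events["onset_sample"].to_numpy()
    if len(onsets) >= 2 and np.any(np.diff(onsets) < 0):
        raise ValueError("event onsets must be non-decreasing")
    if np.any(events["duration_ms"].to_numpy() < 0):
        raise ValueError("event durations must be non-negative")
    return events


def empty_events() -> pd.DataFrame:
    """An empty event table with the canonical columns."""
    return pd.DataFrame({c: pd.Series(dtype=object if c in ("event_type", "aoi") else float)
                         for c in EVENT_COLUMNS})


# --------------------------------------------------------------------------
# EEG readers / writers
# --------------------------------------------------------------------------

def write_eeg(path: str | Path, eeg: ContinuousEEG, format: str = "brainvision") -> Path:
    """Write EEG to disk.

    ``brainvision`` writes ``.vhdr/.vmrk/.eeg`` with multiplexed IEEE
    float32 samples in microvolts (resolution 1). ``edf`` writes a minimal
    EDF file with one data record and 16-bit quantisation over the data's
    physical range (round-trip error bounded by range / 2**16).

    Parameters
    ----------
    path
        Destination; extension is replaced as needed.
    """
    path = Path(path)
    if format == "brainvision":
        return _write_brainvision(path, eeg)
    if format == "edf":
        return _write_edf(path, eeg)
    raise ValueError(f"unknown EEG format {format!r}")


def _write_brainvision(path: Path, eeg: ContinuousEEG) -> Path:
    vhdr = path.with_suffix(".vhdr")
    vmrk = path.with_suffix(".vmrk")
    data_file = path.with_suffix(".eeg")
    sampling_interval_us = 1e6 / eeg.rate
    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "; Written by fixerp",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={data_file.name}",
        f"MarkerFile={vmrk.name}",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={eeg.n_channels}",
        f"SamplingInterval={sampling_interval_us:g}",
        "",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "",
        "[Channel Infos]",
    ]
    for i, name in enumerate(eeg.channel_names, start=1):
        lines.append(f"Ch{i}={name},{eeg.reference if eeg.reference != 'average' else ''},1,µV")
    vhdr.write_text("\n".join(lines) + "\n", encoding="utf-8")
    vmrk.write_text(
        "\n".join([
            "Brain Vision Data Exchange Marker File, Version 1.0",
            "",
            "[Common Infos]",
            "Codepage=UTF-8",
            f"DataFile={data_file.name}",
            "",
            "[Marker Infos]",
            "Mk1=New Segment,,1,1,0,00000000000000000000",
        ]) + "\n",
        encoding="utf-8",
    )
    # multiplexed: sample-major, channel-minor
    eeg.data.T.astype("<f4").tofile(data_file)
    return vhdr


def _write_edf(path: Path, eeg: ContinuousEEG) -> Path:
    """Minimal EDF writer: one data record holding the whole signal."""
    path = path.with_suffix(".edf")
    n_ch = eeg.n_channels
    n_samp = eeg.n_samples
    duration = n_samp / eeg.rate
    dur_str = f"{duration:.8g}"[:8]
    if abs(float(dur_str) - duration) > 1e-9:
        raise ValueError("recording duration not representable in EDF header")

    header = bytearray()

    def put(text: str, width: int) -> None:
        b = text.encode("ascii")
        if len(b) > width:
            raise ValueError(f"EDF field too long: {text!r}")
        header.extend(b.ljust(width))

    put("0", 8)                       # version
    put("X X X X", 80)                # patient id
    put("Startdate X X X X", 80)      # recording id
    put("01.01.00", 8)
    put("00.00.00", 8)
    put(str(256 * (n_ch + 1)), 8)     # header bytes
    put("", 44)
    put("1", 8)                       # number of data records
    put(dur_str, 8)                   # record duration (s)
    put(str(n_ch), 4)

    phys_min = np.minimum(eeg.data.min(axis=1), -1.0)
    phys_max = np.maximum(eeg.data.max(axis=1), 1.0)
    for name in eeg.channel_names:
        put(name, 16)
    for _ in range(n_ch):
        put("Active electrode", 80)
    for _ in range(n_ch):
        put("uV", 8)
    for lo in phys_min:
        put(f"{lo:.6g}"[:8], 8)
    for hi in phys_max:
        put(f"{hi:.6g}"[:8], 8)
    for _ in range(n_ch):
        put("-32768", 8)
    for _ in range(n_ch):
        put("32767", 8)
    for _ in range(n_ch):
        put("", 80)                   # prefiltering
    for _ in range(n_ch):
        put(str(n_samp), 8)
    for _ in range(n_ch):
        put("", 32)

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        for ch in range(n_ch):
            lo, hi = phys_min[ch], phys_max[ch]
            scaled = (eeg.data[ch] - lo) / (hi - lo) * 65535.0 - 32768.0
            fh.write(np.round(scaled).astype("<i2").tobytes())
    return path


def _check_brainvision_header(vhdr: Path) -> None:
    """Pre-flight sanity check so malformed headers fail with a named field."""
    parser = configparser.ConfigParser(strict=False)
    text = vhdr.read_text(encoding="utf-8", errors="replace")
    # strip the magic line(s) before INI parsing
    body = "\n".join(ln for ln in text.splitlines() if not ln.startswith("Brain Vision"))
    try:
        parser.read_string(body)
    except configparser.Error as exc:
        raise FormatError(f"unparseable BrainVision header: {exc}") from exc
    common = {k.lower(): v for k, v in parser.items("Common Infos")} \
        if parser.has_section("Common Infos") else {}
    for field_name in ("datafile", "numberofchannels", "samplinginterval"):
        if field_name not in common:
            raise FormatError(f"BrainVision header missing field {field_name!r}")
    try:
        n_ch = int(common["numberofchannels"])
    except ValueError:
        raise FormatError("BrainVision field 'NumberOfChannels' is not an integer")
    if not parser.has_section("Channel Infos"):
        raise FormatError("BrainVision header missing field 'Channel Infos'")
    chans = [v.split(",")[0] for _, v in parser.items("Channel Infos")]
    if len(chans) != n_ch:
        raise FormatError(
            f"BrainVision field 'NumberOfChannels' ({n_ch}) does not match "
            f"the {len(chans)} entries in 'Channel Infos'"
        )
    if len(set(chans)) != len(chans):
        raise FormatError("BrainVision field 'Channel Infos' has duplicate channel names")


def read_eeg(path: str | Path, format: str | None = None) -> ContinuousEEG:
    """Read a BrainVision or EDF recording into a :class:`ContinuousEEG`.

    The format is inferred from the extension unless given. Data are
    converted to microvolts.
    """
    import mne

    path = Path(path)
    if format is None:
        format = {".vhdr": "brainvision", ".edf": "edf"}.get(path.suffix.lower())
        if format is None:
            raise ValueError(f"cannot infer EEG format from {path.name!r}")
    if not path.exists():
        raise FileNotFoundError(path)

    if format == "brainvision":
        _check_brainvision_header(path)
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
        reference = "FCz"
    elif format == "edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        reference = "unknown"
    else:
        raise ValueError(f"unknown EEG format {format!r}")

    data_uv = raw.get_data() * 1e6
    names = tuple(raw.ch_names)
    if len(set(names)) != len(names):
        raise FormatError("duplicate channel names in EEG file")
    return ContinuousEEG(data_uv, float(raw.info["sfreq"]), names, reference=reference)


# --------------------------------------------------------------------------
# Gaze and event tables
# --------------------------------------------------------------------------

def write_gaze(path: str | Path, gaze: GazeStream) -> Path:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.DataFrame({"t": gaze.t, "x": gaze.x, "y": gaze.y, "aoi": gaze.aoi})
    df.to_csv(path, sep=sep, index=False)
    return path


def read_gaze(path: str | Path, rate: float | None = None, unit: str = "deg") -> GazeStream:
    """Read a gaze CSV/TSV with columns ``t, x, y, aoi``.

    The sampling rate is estimated from the median timestamp step when not
    given. Unknown AOI strings raise with the allowed label set.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    missing = {"t", "x", "y", "aoi"} - set(df.columns)
    if missing:
        raise FormatError(f"gaze file missing columns {sorted(missing)}")
    if rate is None:
        dt = np.median(np.diff(df["t"].to_numpy())) if len(df) >= 2 else 1.0
        # non-positive dt is caught by GazeStream's monotonicity check
        rate = 1.0 / dt if dt > 0 else 1.0
    return GazeStream(
        df["t"].to_numpy(float), df["x"].to_numpy(float), df["y"].to_numpy(float),
        df["aoi"].astype(str).to_numpy(), rate=float(rate), unit=unit,
    )


def write_events(path: str | Path, events: pd.DataFrame, rate: float) -> Path:
    """Write events as a BIDS-events-like TSV (onset in seconds)."""
    validate_events(events)
    out = pd.DataFrame({
        "onset": events["onset_sample"].to_numpy(float) / rate,
        "duration": events["duration_ms"].to_numpy(float) / 1000.0,
        "trial_type": events["event_type"],
        "aoi": events["aoi"],
        "sacc_amplitude": events["prior_saccade_amplitude"].where(
            events["event_type"] == "fixation", events["amplitude"]),
        "peak_velocity": events["peak_velocity"],
    })
    path = Path(path)
    out.to_csv(path, sep="\t", index=False, na_rep="n/a")
    return path


def read_events(path: str | Path, rate: float) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["n/a"])
    is_fix = df["trial_type"] == "fixation"
    events = pd.DataFrame({
        "event_type": df["trial_type"],
        "onset_sample": np.round(df["onset"].to_numpy(float) * rate).astype(int),
        "duration_ms": df["duration"].to_numpy(float) * 1000.0,
        "aoi": df["aoi"].fillna("none"),
        "amplitude": df["sacc_amplitude"].where(~is_fix),
        "peak_velocity": df["peak_velocity"],
        "prior_saccade_amplitude": df["sacc_amplitude"].where(is_fix),
    })
    return validate_events(events)


# --------------------------------------------------------------------------
# Signal conditioning
# --------------------------------------------------------------------------

def bandpass(eeg: ContinuousEEG, low_hz: float, high_hz: float) -> ContinuousEEG:
    """Zero-phase FIR band-pass filter (Hamming design).

    Transition bandwidths are 25 % of the respective band edge, which keeps
    attenuation one octave outside the band well beyond 20 dB.
    """
    import mne

    nyq = eeg.rate / 2.0
    if not (0 < low_hz < high_hz < nyq):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz must satisfy 0 < low < high < "
            f"Nyquist ({nyq} Hz)"
        )
    filtered = mne.filter.filter_data(
        eeg.data, sfreq=eeg.rate, l_freq=low_hz, h_freq=high_hz,
        l_trans_bandwidth=0.25 * low_hz, h_trans_bandwidth=0.25 * high_hz,
        fir_design="firwin", fir_window="hamming", phase="zero",
        verbose="error",
    )
    return replace(eeg, data=filtered)


def resample(eeg: ContinuousEEG, target_rate: float) -> ContinuousEEG:
    """Downsample EEG with polyphase anti-alias filtering.

    Only downsampling is supported here; upsampling is a gaze-stream
    operation (:func:`fixerp.sync.upsample_gaze`).
    """
    from scipy.signal import resample_poly

    if target_rate > eeg.rate:
        raise ValueError(
            f"cannot upsample EEG from {eeg.rate} to {target_rate} Hz; "
            "only gaze is upsampled"
        )
    if target_rate == eeg.rate:
        return eeg.copy()
    frac = Fraction(target_rate / eeg.rate).limit_denominator(1000)
    data = resample_poly(eeg.data, frac.numerator, frac.denominator, axis=1)
    return replace(eeg, data=data, rate=eeg.rate * frac.numerator / frac.denominator)


def rereference_average(eeg: ContinuousEEG) -> ContinuousEEG:
    """Re-reference to the average of all delivered channels.

    Idempotent; requires at least two channels.
    """
    if eeg.n_channels < 2:
        raise ValueError("average reference requires at least 2 channels")
    data = eeg.data - eeg.data.mean(axis=0, keepdims=True)
    return replace(eeg, data=data, reference="average")
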
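"""ERP component extraction: cluster averages, grand-average anchoring,
subject-level peak search, and late-positive-component window means.

Peak extraction mirrors the two-stage procedure used in FRP studies:
a single anchor latency per component is located on the grand-average
waveform (conditions pooled), then each subject-by-condition waveform is
searched for local extrema of the component's polarity within ±30 ms of
the anchor, keeping the peak whose latency is *closest* to the anchor (not
the largest). Absent peaks are a first-class outcome (``found=False``) and
are excluded from statistics rather than imputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CLUSTERS
from .deconv import ErpWaveform

__all__ = [
    "ComponentDef",
    "PeakEstimate",
    "DEFAULT_COMPONENTS",
    "cluster_average",
    "grand_average",
    "find_component_peak",
    "extract_subject_peak",
    "lpc_mean",
]


@dataclass
class ComponentDef:
    """Search definition for one ERP component.

    ``polarity`` is ``"positive"``/``"negative"`` for peaked components and
    ``None`` for window-mean components (LPC).
    """

    name: str
    cluster: str
    polarity: str | None
    window_ms: tuple[float, float]

    def __post_init__(self) -> None:
        if self.window_ms[0] >= self.window_ms[1]:
            raise ValueError("window start must precede end")
        if self.cluster not in CLUSTERS:
            raise ValueError(f"unknown cluster {self.cluster!r}")


#: Default component set: lambda/P1 and N1 occipitally, P200 over parietal
#: and frontal clusters, and the parietal LPC as a 500–800 ms window mean.
DEFAULT_COMPONENTS = (
    ComponentDef("P1", "occipital", "positive", (60.0, 130.0)),
    ComponentDef("N1", "occipital", "negative", (120.0, 200.0)),
    ComponentDef("P200_parietal", "parietal", "positive", (150.0, 250.0)),
    ComponentDef("P200_frontal", "frontal", "positive", (120.0, 200.0)),
    ComponentDef("LPC", "parietal", None, (500.0, 800.0)),
)


@dataclass
class PeakEstimate:
    subject: str
    condition: str
    component: str
    amplitude: float
    latency_ms: float
    found: bool


def cluster_average(erp: ErpWaveform, cluster: str) -> ErpWaveform:
    """Unweighted mean over the member channels of an electrode cluster."""
    if cluster not in CLUSTERS:
        raise ValueError(f"unknown cluster {cluster!r}")
    if erp.values.ndim != 2 or erp.channel_names is None:
        raise ValueError("cluster_average needs a multichannel waveform")
    idx = []
    for member in CLUSTERS[cluster]:
        if member not in erp.channel_names:
            raise ValueError(f"cluster {cluster!r} member {member!r} missing "
                             "from waveform channels")
        idx.append(erp.channel_names.index(member))
    return ErpWaveform(erp.values[idx].mean(axis=0), erp.lags_ms.copy(),
                       None, label=f"{erp.label}:{cluster}",
                       baseline_corrected=erp.baseline_corrected)


def grand_average(waveforms: list[ErpWaveform]) -> ErpWaveform:
    """Unweighted mean over subject waveforms sharing one lag axis."""
    if not waveforms:
        raise ValueError("no waveforms to average")
    lags = waveforms[0].lags_ms
    for w in waveforms[1:]:
        if len(w.lags_ms) != len(lags) or not np.allclose(w.lags_ms, lags):
            raise ValueError("waveforms have mismatching lag axes")
    stack = np.stack([w.values for w in waveforms])
    return ErpWaveform(stack.mean(axis=0), lags.copy(),
                       waveforms[0].channel_names, label="grand_average",
                       baseline_corrected=waveforms[0].baseline_corrected)


def _local_extrema(values: np.ndarray, kind: str) -> list[int]:
    """Indices of strict local maxima/minima; plateaus yield their midpoint."""
    v = values if kind == "max" else -values
    idx = []
    n = len(v)
    i = 1
    while i < n - 1:
        if v[i] > v[i - 1]:
            j = i
            while j < n - 1 and v[j + 1] == v[j]:
                j += 1
            if j < n - 1 and v[j + 1] < v[j]:
                idx.append((i + j) // 2)
            i = j + 1
        else:
            i += 1
    return idx


def find_component_peak(grand: ErpWaveform, component: ComponentDef) -> float:
    """Anchor latency: the polarity-appropriate extremum on the grand average.

    Only local extrema strictly inside the search window qualify; among
    them the one with the largest polarity-signed amplitude wins. Raises if
    the window contains no extremum of the right polarity — a prompt to
    review the window.
    """
    if grand.values.ndim != 1:
        raise ValueError("anchoring expects a single (cluster) waveform")
    lo, hi = component.window_ms
    if lo < grand.lags_ms[0] or hi > grand.lags_ms[-1]:
        raise ValueError(f"search window {component.window_ms} outside lag axis")
    kind = "max" if component.polarity == "positive" else "min"
    cand = [i for i in _local_extrema(grand.values, kind)
            if lo <= grand.lags_ms[i] <= hi]
    if not cand:
        raise ValueError(
            f"no {component.polarity} local extremum for {component.name} in "
            f"{component.window_ms} ms — review the search window"
        )
    sign = 1.0 if component.polarity == "positive" else -1.0
    best = max(cand, key=lambda i: sign * grand.values[i])
    return float(grand.lags_ms[best])


def extract_subject_peak(waveform: ErpWaveform, anchor_ms: float,
                         component: ComponentDef, subject: str = "",
                         condition: str = "",
                         tolerance_ms: float = 30.0) -> PeakEstimate:
    """Subject peak: the polarity extremum *closest* to the anchor (±30 ms).

    A window without a qualifying local extremum yields ``found=False``
    with NaN amplitude/latency — missingness is data, not an error.
    """
    if waveform.values.ndim != 1:
        raise ValueError("peak extraction expects a single (cluster) waveform")
    kind = "max" if component.polarity == "positive" else "min"
    cand = [i for i in _local_extrema(waveform.values, kind)
            if abs(waveform.lags_ms[i] - anchor_ms) <= tolerance_ms]
    if not cand:
        return PeakEstimate(subject, condition, component.name,
                            np.nan, np.nan, found=False)
    best = min(cand, key=lambda i: abs(waveform.lags_ms[i] - anchor_ms))
    return PeakEstimate(subject, condition, component.name,
                        float(waveform.values[best]),
                        float(waveform.lags_ms[best]), found=True)


def lpc_mean(waveform: ErpWaveform,
             window_ms: tuple[float, float] = (500.0, 800.0)) -> float:
    """Mean amplitude over the LPC window (inclusive bounds)."""
    if waveform.values.ndim != 1:
        raise ValueError("lpc_mean expects a single (cluster) waveform")
    lo, hi = window_ms
    eps = 1e-9
    if lo < waveform.lags_ms[0] - eps or hi > waveform.lags_ms[-1] + eps:
        raise ValueError(f"lag axis does not cover the {window_ms} ms window")
    mask = (waveform.lags_ms >= lo - eps) & (waveform.lags_ms <= hi + eps)
    return float(waveform.values[mask].mean())
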
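"""End-to-end orchestration: simulate → sync → events → deconv → components → stats.

`run_pipeline` drives the whole analysis on a simulated cohort from a
validated configuration and returns (optionally writes) per-subject
artifacts, a component peak table, a cohort peak-summary table (mean
amplitude and latency per component x condition), and the mixed-model
outputs. All randomness flows from the single master seed, so two runs
with the same configuration produce identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from . import __version__
from .core import (AOI_CONDITIONS, CLUSTERS, ContinuousEEG,
                   bandpass, rereference_average, resample, write_events)
from .synth import (EYE_CHANNEL, CohortConfig, NoiseParams, ScanpathParams,
                    SubjectRecording, generate_cohort)
from .sync import apply_lag, estimate_lag, gaze_on_grid, upsample_gaze
from .oculomotor import DetectionParams, detect_events
from .deconv import DeconvSpec, DeconvFit, build_design, fit, reconstruct_erp
from .components import (DEFAULT_COMPONENTS, ComponentDef, PeakEstimate,
                         cluster_average, extract_subject_peak,
                         find_component_peak, grand_average, lpc_mean)
from .stats import LmmResult, build_model_frame, fit_lmm, pairwise_by_gender

__all__ = ["PipelineConfig", "run_pipeline", "process_subject",
           "analyze_cohort", "summarize_table1", "PipelineResult"]

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# Configuration schema (unknown keys rejected, validated before compute)
# --------------------------------------------------------------------------

class SimulationBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_subjects: int = 6
    duration_s: float = 210.0
    delta_abstract: float = -0.02
    delta_realistic: float = 0.28
    pink_sd: float = 3.0
    white_sd: float = 1.0
    offset_range_ms: tuple[float, float] = (134.0, 1776.0)


class FilterBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    low_hz: float = 1.0
    high_hz: float = 30.0
    analysis_rate: float = 250.0


class DetectionBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    lambda_multiplier: float = 6.0
    min_saccade_samples: int = 4
    min_fix_ms: float = 150.0
    max_fix_ms: float = 2000.0

    @model_validator(mode="after")
    def _check_bounds(self):
        if self.max_fix_ms <= self.min_fix_ms:
            raise ValueError("max_fix_ms must exceed min_fix_ms")
        return self


class DeconvBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    fix_window_ms: tuple[float, float] = (-200.0, 800.0)
    step_window_ms: tuple[float, float] = (-200.0, 600.0)
    n_spline: int = 5
    ridge: float = 0.0


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    out_dir: str | None = None
    max_lag_s: float = 10.0
    simulation: SimulationBlock = SimulationBlock()
    filter: FilterBlock = FilterBlock()
    detection: DetectionBlock = DetectionBlock()
    deconv: DeconvBlock = DeconvBlock()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.model_validate(raw)


# --------------------------------------------------------------------------
# Per-subject processing
# --------------------------------------------------------------------------

@dataclass
class SubjectResult:
    subject: str
    gender: str
    lag_ms: float
    peak_correlation: float
    events: pd.DataFrame
    fit: DeconvFit
    #: condition -> cluster -> ErpWaveform (baseline-corrected)
    waveforms: dict


def preprocess(eeg: ContinuousEEG, low_hz: float = 1.0, high_hz: float = 30.0,
               analysis_rate: float = 250.0) -> ContinuousEEG:
    """Band-pass, downsample, and average-rereference the scalp channels.

    The horizontal-eye nuisance channel (if present) is filtered and
    resampled with the rest but excluded from — and untouched by — the
    average reference.
    """
    out = bandpass(eeg, low_hz, high_hz)
    out = resample(out, analysis_rate)
    if EYE_CHANNEL in out.channel_names:
        eye_idx = out.channel_names.index(EYE_CHANNEL)
        scalp_idx = [i for i in range(out.n_channels) if i != eye_idx]
        scalp = ContinuousEEG(out.data[scalp_idx], out.rate,
                              tuple(out.channel_names[i] for i in scalp_idx),
                              reference=out.reference)
        scalp = rereference_average(scalp)
        data = np.vstack([scalp.data, out.data[eye_idx][None, :]])
        return ContinuousEEG(data, out.rate,
                             scalp.channel_names + (EYE_CHANNEL,),
                             reference="average")
    return rereference_average(out)


def process_subject(rec: SubjectRecording, config: PipelineConfig) -> SubjectResult:
    """Run preprocessing, synchronization, event parsing, and deconvolution."""
    cfg = config
    eeg = preprocess(rec.eeg, cfg.filter.low_hz, cfg.filter.high_hz,
                     cfg.filter.analysis_rate)
    rate = eeg.rate

    eye = eeg.channel(EYE_CHANNEL)
    gx = gaze_on_grid(rec.gaze, rate, eeg.n_samples)
    lag = estimate_lag(eye, gx, rate, max_lag_ms=cfg.max_lag_s * 1000.0)
    gaze = upsample_gaze(apply_lag(rec.gaze, lag.lag_ms), rate)

    det = DetectionParams(
        lambda_multiplier=cfg.detection.lambda_multiplier,
        min_saccade_samples=cfg.detection.min_saccade_samples,
        min_fix_ms=cfg.detection.min_fix_ms,
        max_fix_ms=cfg.detection.max_fix_ms,
    )
    events = detect_events(gaze, det)
    # gait events come from the recording's step annotations (rescaled)
    steps = rec.truth.events.query("event_type == 'step'")[
        ["event_type", "onset_sample", "duration_ms", "aoi", "amplitude",
         "peak_velocity", "prior_saccade_amplitude"]].copy()
    steps["onset_sample"] = np.round(
        steps["onset_sample"] * rate / rec.eeg.rate).astype(int)
    events = pd.concat([events, steps], ignore_index=True)
    events = events.sort_values("onset_sample", kind="stable").reset_index(drop=True)

    spec = DeconvSpec(rate=rate, fix_window_ms=cfg.deconv.fix_window_ms,
                      step_window_ms=cfg.deconv.step_window_ms,
                      n_spline=cfg.deconv.n_spline, ridge=cfg.deconv.ridge)
    scalp_idx = [i for i, ch in enumerate(eeg.channel_names) if ch != EYE_CHANNEL]
    scalp = ContinuousEEG(eeg.data[scalp_idx], rate,
                          tuple(eeg.channel_names[i] for i in scalp_idx),
                          reference=eeg.reference)
    design = build_design(events, spec, scalp.n_samples)
    fitted = fit(scalp, design)

    waveforms = {}
    for cond in AOI_CONDITIONS:
        erp = reconstruct_erp(fitted, cond)
        waveforms[cond] = {cl: cluster_average(erp, cl) for cl in CLUSTERS}

    n_fix = int((events["event_type"] == "fixation").sum())
    logger.info("%s: lag %.1f ms (r=%.2f), %d fixations, %d design columns",
                rec.subject, lag.lag_ms, lag.peak_correlation, n_fix,
                design.X.shape[1])
    return SubjectResult(rec.subject, rec.meta["gender"], lag.lag_ms,
                         lag.peak_correlation, events, fitted, waveforms)


# --------------------------------------------------------------------------
# Cohort-level analysis
# --------------------------------------------------------------------------

@dataclass
class PipelineResult:
    subjects: list
    anchors: dict
    peaks: pd.DataFrame
    table1: pd.DataFrame
    models: dict
    pairwise: dict
    manifest: dict = field(default_factory=dict)


def analyze_cohort(results: list[SubjectResult],
                   components: tuple[ComponentDef, ...] = DEFAULT_COMPONENTS
                   ) -> PipelineResult:
    """Anchor components on the pooled grand average, extract peaks, model.

    A single anchor latency per component is found on the grand average
    over all subjects and conditions; each subject-by-condition waveform is
    then searched within ±30 ms of that anchor.
    """
    anchors: dict[str, float] = {}
    rows: list[PeakEstimate] = []
    for comp in components:
        pooled = [res.waveforms[cond][comp.cluster]
                  for res in results for cond in AOI_CONDITIONS]
        if comp.polarity is not None:
            anchors[comp.name] = find_component_peak(grand_average(pooled), comp)
        for res in results:
            for cond in AOI_CONDITIONS:
                wave = res.waveforms[cond][comp.cluster]
                if comp.polarity is None:
                    rows.append(PeakEstimate(res.subject, cond, comp.name,
                                             lpc_mean(wave, comp.window_ms),
                                             np.nan, found=True))
                else:
                    rows.append(extract_subject_peak(
                        wave, anchors[comp.name], comp,
                        subject=res.subject, condition=cond))

    gender = {res.subject: res.gender for res in results}
    peaks = pd.DataFrame([dict(
        subject=p.subject, gender=gender[p.subject], condition=p.condition,
        component=p.component, amplitude=p.amplitude, latency_ms=p.latency_ms,
        found=p.found) for p in rows])

    models: dict = {}
    pairwise: dict = {}
    for comp in components:
        sub = peaks[peaks["component"] == comp.name]
        models[comp.name] = {}
        try:
            amp = fit_lmm(build_model_frame(sub, "amplitude"))
            models[comp.name]["amplitude"] = amp
            if amp.converged:
                pairwise[comp.name] = pairwise_by_gender(amp)
        except ValueError as exc:
            logger.warning("%s amplitude model skipped: %s", comp.name, exc)
        if comp.polarity is not None:
            try:
                models[comp.name]["latency"] = fit_lmm(
                    build_model_frame(sub, "latency_ms"))
            except ValueError as exc:
                logger.warning("%s latency model skipped: %s", comp.name, exc)

    return PipelineResult(results, anchors, peaks, summarize_table1(peaks),
                          models, pairwise)


def summarize_table1(peaks: pd.DataFrame) -> pd.DataFrame:
    """Mean amplitude (µV) and latency (ms) per component x condition.

    Rows with ``found=False`` are excluded from both the means and the
    reported n.
    """
    found = peaks[peaks["found"].astype(bool)]
    out = (found.groupby(["component", "condition"], sort=True)
           .agg(mean_amplitude_uv=("amplitude", "mean"),
                mean_latency_ms=("latency_ms", "mean"),
                n_found=("amplitude", "size"))
           .reset_index())
    return out


# --------------------------------------------------------------------------
# Entry point
# --------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig | dict | str | Path) -> PipelineResult:
    """Simulate a cohort and run the full analysis per the configuration."""
    if isinstance(config, (str, Path)):
        config = PipelineConfig.from_yaml(config)
    elif isinstance(config, dict):
        config = PipelineConfig.model_validate(config)

    sim = config.simulation
    cohort_cfg = CohortConfig(
        duration_s=sim.duration_s,
        noise=NoiseParams(pink_sd=sim.pink_sd, white_sd=sim.white_sd),
        offset_range_ms=sim.offset_range_ms,
        delta_abstract=sim.delta_abstract,
        delta_realistic=sim.delta_realistic,
    )
    cohort = generate_cohort(sim.n_subjects, cohort_cfg, seed=config.seed)

    results = []
    for rec in cohort:
        try:
            results.append(process_subject(rec, config))
        except Exception as exc:
            raise RuntimeError(
                f"pipeline failed at subject {rec.subject}: {exc}") from exc

    out = analyze_cohort(results)
    out.manifest = _manifest(config, out)
    if config.out_dir:
        write_outputs(out, config.out_dir, results)
    return out


def _manifest(config: PipelineConfig, result: PipelineResult) -> dict:
    import scipy
    import statsmodels

    return {
        "fixerp_version": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
        "config": json.loads(config.model_dump_json()),
        "anchors_ms": result.anchors,
        "n_subjects": len(result.subjects),
    }


def write_outputs(result: PipelineResult, out_dir: str | Path,
                  subjects: list[SubjectResult]) -> None:
    """Write the results bundle: per-subject artifacts + group tables."""
    out = Path(out_dir)
    (out / "group").mkdir(parents=True, exist_ok=True)
    for res in subjects:
        sub_dir = out / res.subject
        sub_dir.mkdir(parents=True, exist_ok=True)
        (sub_dir / "lag.json").write_text(json.dumps(
            {"lag_ms": res.lag_ms, "peak_correlation": res.peak_correlation}))
        write_events(sub_dir / "events.tsv", res.events, res.fit.spec.rate)
        for cond, clusters in res.waveforms.items():
            frame = pd.DataFrame(
                {"lag_ms": next(iter(clusters.values())).lags_ms,
                 **{cl: w.values for cl, w in clusters.items()}})
            frame.to_csv(sub_dir / f"erp_{cond}.tsv", sep="\t", index=False)
    result.peaks.to_csv(out / "group" / "peaks.tsv", sep="\t", index=False)
    result.table1.to_csv(out / "group" / "summary.tsv", sep="\t", index=False)
    model_rows = []
    for comp, fits in result.models.items():
        for measure, lmm in fits.items():
            t = lmm.terms.copy()
            t.insert(0, "measure", measure)
            t.insert(0, "component", comp)
            model_rows.append(t)
    if model_rows:
        pd.concat(model_rows).to_csv(out / "group" / "models.tsv",
                                     sep="\t", index=False)
    for comp, table in result.pairwise.items():
        table.to_csv(out / "group" / f"pairwise_{comp}.tsv", sep="\t",
                     index=False)
    (out / "group" / "manifest.json").write_text(
        json.dumps(result.manifest, indent=2, default=str))
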
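"""Time-expanded regression (deconvolution) of overlapping evoked responses.

Fixation-locked brain responses during free viewing overlap in time because
fixations follow each other every few hundred milliseconds. Modelling the
continuous EEG as a linear superposition of event-locked kernels —
``y(t) = sum_events sum_lags X[t, (predictor, lag)] * b[(predictor, lag)]``
— and solving the least-squares problem separates the overlapping
responses (the regression-ERP / "unfolding" approach).

The design here uses stick (FIR) predictors: fixation intercept
(Environment baseline), treatment dummies for the LM-Abstract and
LM-Realistic conditions, a centered cubic B-spline expansion of the prior
saccade amplitude (capturing the nonlinear lambda-response gain), and a
step-event intercept for gait artifacts. Condition ERPs are reconstructed
from coefficients and baseline-corrected over [-200, 0] ms.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.interpolate import BSpline

from .core import AOI_CONDITIONS, ContinuousEEG

__all__ = [
    "DeconvSpec",
    "SplineBasis",
    "DesignMatrix",
    "DeconvFit",
    "ErpWaveform",
    "spline_basis",
    "build_design",
    "fit",
    "reconstruct_erp",
    "baseline_correct",
    "epoch_average",
    "save_fit",
    "load_fit",
]

logger = logging.getLogger(__name__)


@dataclass
class DeconvSpec:
    """Windows and predictor set of the time-expanded model."""

    rate: float = 250.0
    fix_window_ms: tuple[float, float] = (-200.0, 800.0)
    step_window_ms: tuple[float, float] = (-200.0, 600.0)
    # short saccade window: just enough to absorb the spike potential
    # without going collinear with the fixation sticks
    sacc_window_ms: tuple[float, float] = (-40.0, 80.0)
    n_spline: int = 5
    include_steps: bool = True
    include_saccades: bool = True
    include_aoi: bool = True
    include_spline: bool = True
    ridge: float = 0.0

    def __post_init__(self) -> None:
        for w in (self.fix_window_ms, self.step_window_ms,
                  self.sacc_window_ms):
            if not (w[0] <= 0.0 <= w[1]):
                raise ValueError(f"event window {w} must contain 0")
        if self.n_spline < 3:
            raise ValueError("n_spline must be >= 3")

    def lag_range(self, window_ms: tuple[float, float]) -> tuple[int, int]:
        lo = int(round(window_ms[0] / 1000.0 * self.rate))
        hi = int(round(window_ms[1] / 1000.0 * self.rate))
        return lo, hi

    @property
    def fix_lags(self) -> np.ndarray:
        lo, hi = self.lag_range(self.fix_window_ms)
        return np.arange(lo, hi + 1)

    @property
    def step_lags(self) -> np.ndarray:
        lo, hi = self.lag_range(self.step_window_ms)
        return np.arange(lo, hi + 1)

    @property
    def sacc_lags(self) -> np.ndarray:
        lo, hi = self.lag_range(self.sacc_window_ms)
        return np.arange(lo, hi + 1)


# --------------------------------------------------------------------------
# Spline basis for the prior-saccade-amplitude covariate
# --------------------------------------------------------------------------

@dataclass
class SplineBasis:
    """Centered cubic B-spline basis over saccade amplitudes.

    Knots sit at amplitude quantiles; every basis row is centered by its
    value at ``reference`` (so the model intercept is the ERP at the
    reference amplitude) and one column — the one largest at the reference
    — is dropped to remove the exact collinearity with the intercept that
    centering a partition of unity creates.
    """

    knots: np.ndarray
    degree: int
    reference: float
    drop_index: int
    n_basis: int

    @property
    def n_cols(self) -> int:
        return self.n_basis - 1

    def raw(self, amplitudes: np.ndarray) -> np.ndarray:
        """Uncentered basis (rows sum to 1 inside the knot span)."""
        a = np.clip(np.asarray(amplitudes, dtype=float),
                    self.knots[0], self.knots[-1])
        return BSpline.design_matrix(a, self.knots, self.degree).toarray()

    def transform(self, amplitudes: np.ndarray) -> np.ndarray:
        """Centered basis with the collinear column removed."""
        b = self.raw(np.atleast_1d(amplitudes))
        b = b - self.raw(np.array([self.reference]))
        return np.delete(b, self.drop_index, axis=1)


def spline_basis(amplitudes: np.ndarray, n_basis: int = 5,
                 reference_amplitude: float | None = None) -> SplineBasis:
    """Build the amplitude spline basis from observed amplitudes.

    ``reference_amplitude`` defaults to the median amplitude. Raises if
    there are fewer distinct amplitude values than basis functions.
    """
    a = np.asarray(amplitudes, dtype=float)
    a = a[np.isfinite(a)]
    if len(np.unique(a)) < n_basis:
        raise ValueError(
            f"need at least {n_basis} distinct amplitudes for {n_basis} "
            f"basis functions, got {len(np.unique(a))}"
        )
    degree = min(3, n_basis - 1)
    n_interior = n_basis - degree - 1
    lo, hi = float(a.min()), float(a.max())
    if n_interior > 0:
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(a, qs)
    else:
        interior = np.array([])
    knots = np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])
    ref = float(np.median(a)) if reference_amplitude is None else float(reference_amplitude)
    basis = SplineBasis(knots, degree, ref, drop_index=0, n_basis=n_basis)
    at_ref = basis.raw(np.array([ref]))[0]
    basis.drop_index = int(np.argmax(at_ref))
    return basis


# --------------------------------------------------------------------------
# Design matrix
# --------------------------------------------------------------------------

@dataclass
class DesignMatrix:
    X: sp.csr_matrix
    columns: pd.DataFrame       # predictor, basis, lag_index, lag_ms per column
    spec: DeconvSpec
    spline: SplineBasis | None
    reference_amplitude: float | None
    n_fixations: int
    n_steps: int
    n_dropped: int


def build_design(events: pd.DataFrame, spec: DeconvSpec, n_samples: int,
                 spline: SplineBasis | None = None) -> DesignMatrix:
    """Time-expanded sparse design matrix over the whole recording.

    Fixations contribute an intercept stick, treatment dummies vs the
    Environment baseline, and the centered amplitude-spline sticks; saccade
    and step events contribute intercept sticks over their own windows (the
    saccade stick captures the spike potential that would otherwise bias
    the fixation kernel). Fixations without a finite prior-saccade
    amplitude are excluded; events whose window extends beyond the
    recording are dropped (count logged).
    """
    fix = events[(events["event_type"] == "fixation")].copy()
    n_missing_prior = 0
    if spec.include_spline:
        n_missing_prior = int((~np.isfinite(
            fix["prior_saccade_amplitude"].to_numpy(float))).sum())
        fix = fix[np.isfinite(fix["prior_saccade_amplitude"].to_numpy(float))]
    steps = events[events["event_type"] == "step"] if spec.include_steps \
        else events.iloc[0:0]
    saccs = events[events["event_type"] == "saccade"] \
        if spec.include_saccades else events.iloc[0:0]

    fix_lags = spec.fix_lags
    step_lags = spec.step_lags
    sacc_lags = spec.sacc_lags
    n_dropped = 0

    def in_bounds(onsets: np.ndarray, lags: np.ndarray) -> np.ndarray:
        ok = (onsets + lags[0] >= 0) & (onsets + lags[-1] < n_samples)
        return ok

    f_on = fix["onset_sample"].to_numpy(int)
    ok = in_bounds(f_on, fix_lags)
    n_dropped += int((~ok).sum())
    fix = fix[ok]
    f_on = f_on[ok]
    s_on = steps["onset_sample"].to_numpy(int)
    ok_s = in_bounds(s_on, step_lags) if len(s_on) else np.array([], dtype=bool)
    n_dropped += int((~ok_s).sum()) if len(s_on) else 0
    s_on = s_on[ok_s] if len(s_on) else s_on
    sc_on = saccs["onset_sample"].to_numpy(int)
    ok_sc = in_bounds(sc_on, sacc_lags) if len(sc_on) else np.array([], dtype=bool)
    n_dropped += int((~ok_sc).sum()) if len(sc_on) else 0
    sc_on = sc_on[ok_sc] if len(sc_on) else sc_on
    if n_dropped or n_missing_prior:
        logger.info("design: dropped %d out-of-bounds events, excluded %d "
                    "fixations without prior saccade", n_dropped, n_missing_prior)

    aoi = fix["aoi"].to_numpy()
    predictors: list[tuple[str, int, np.ndarray, np.ndarray, np.ndarray]] = []
    # (name, basis_index, event_onsets, event_values, lags)
    predictors.append(("fix_intercept", -1, f_on, np.ones(len(f_on)), fix_lags))
    if spec.include_aoi:
        predictors.append(("fix_abstract", -1, f_on,
                           (aoi == "LM-Abstract").astype(float), fix_lags))
        predictors.append(("fix_realistic", -1, f_on,
                           (aoi == "LM-Realistic").astype(float), fix_lags))
    if spec.include_spline:
        amps = fix["prior_saccade_amplitude"].to_numpy(float)
        if spline is None:
            spline = spline_basis(amps, spec.n_spline)
        spl_vals = spline.transform(amps) if len(amps) \
            else np.zeros((0, spline.n_cols))
        for j in range(spline.n_cols):
            predictors.append(("sacc_amp_spline", j, f_on, spl_vals[:, j], fix_lags))
    else:
        spline = None
    # event-type blocks with no events at all would be all-zero columns
    if spec.include_saccades and len(sc_on):
        predictors.append(("sacc_intercept", -1, sc_on,
                           np.ones(len(sc_on)), sacc_lags))
    if spec.include_steps and len(s_on):
        predictors.append(("step_intercept", -1, s_on,
                           np.ones(len(s_on)), step_lags))

    rows_list, cols_list, vals_list = [], [], []
    col_meta = []
    col_offset = 0
    for name, basis_idx, onsets, values, lags in predictors:
        n_lags = len(lags)
        for li, lag in enumerate(lags):
            col_meta.append(dict(predictor=name, basis=basis_idx, lag_index=li,
                                 lag_ms=lag / spec.rate * 1000.0))
        nz = np.flatnonzero(values != 0.0)
        if len(nz):
            r = (onsets[nz][:, None] + lags[None, :]).ravel()
            c = (col_offset + np.arange(n_lags))[None, :].repeat(len(nz), axis=0).ravel()
            v = np.repeat(values[nz], n_lags)
            rows_list.append(r)
            cols_list.append(c)
            vals_list.append(v)
        col_offset += n_lags

    meta = pd.DataFrame(col_meta)
    if rows_list:
        rows = np.concatenate(rows_list)
        cols = np.concatenate(cols_list)
        vals = np.concatenate(vals_list)
    else:
        rows = cols = vals = np.array([])
    X = sp.coo_matrix((vals, (rows, cols)),
                      shape=(n_samples, col_offset)).tocsr()
    ref = spline.reference if spline is not None else None
    return DesignMatrix(X, meta, spec, spline, ref,
                        n_fixations=len(f_on), n_steps=len(s_on),
                        n_dropped=n_dropped)


# --------------------------------------------------------------------------
# Fitting
# --------------------------------------------------------------------------

@dataclass
class DeconvFit:
    """Per-channel deconvolution coefficients over (predictor x lag)."""

    coef: np.ndarray            # (n_channels, n_columns)
    columns: pd.DataFrame
    spec: DeconvSpec
    spline: SplineBasis | None
    channel_names: tuple[str, ...]
    reference_amplitude: float | None
    residual_variance: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    def block(self, predictor: str, basis: int = -1) -> np.ndarray:
        """Coefficients of one predictor as (n_channels, n_lags)."""
        mask = (self.columns["predictor"] == predictor) & \
               (self.columns["basis"] == basis)
        idx = np.flatnonzero(mask.to_numpy())
        if len(idx) == 0:
            raise KeyError(f"no predictor {predictor!r} (basis {basis})")
        return self.coef[:, idx]

    @property
    def fix_lags_ms(self) -> np.ndarray:
        mask = (self.columns["predictor"] == "fix_intercept").to_numpy()
        return self.columns.loc[mask, "lag_ms"].to_numpy()


def fit(eeg: ContinuousEEG, design: DesignMatrix,
        solver: str = "direct") -> DeconvFit:
    """Least-squares solution of the time-expanded model, all channels.

    ``direct`` (default) solves the normal equations by Cholesky for every
    channel simultaneously; ``lsmr`` runs the iterative sparse solver per
    channel at tolerance 1e-10. Rank-deficient designs fall back to a
    minimum-norm solution with a warning and a diagnostics flag.
    """
    X = design.X
    if X.shape[0] != eeg.n_samples:
        raise ValueError(
            f"design has {X.shape[0]} rows but EEG has {eeg.n_samples} samples"
        )
    Y = eeg.data.T                      # samples x channels
    n, p = X.shape
    diagnostics: dict = {"solver": solver, "n_rows": n, "n_cols": p,
                         "rank_deficient": False}
    ridge = design.spec.ridge

    if solver == "lsmr":
        from scipy.sparse.linalg import lsmr
        coefs = np.empty((eeg.n_channels, p))
        iters = []
        for ch in range(eeg.n_channels):
            res = lsmr(X, Y[:, ch], damp=np.sqrt(ridge) if ridge else 0.0,
                       atol=1e-10, btol=1e-10)
            coefs[ch] = res[0]
            iters.append(int(res[2]))
        diagnostics["lsmr_iterations"] = iters
        B = coefs.T
        XtX = (X.T @ X).toarray()
    elif solver == "direct":
        from scipy.linalg import cho_factor, cho_solve
        XtX = (X.T @ X).toarray()
        if ridge:
            XtX = XtX + ridge * np.eye(p)
        XtY = X.T @ Y
        try:
            c, low = cho_factor(XtX, check_finite=False)
            B = cho_solve((c, low), XtY, check_finite=False)
            # cheap reciprocal condition estimate of X'X
            from scipy.linalg.lapack import dpocon
            anorm = np.linalg.norm(XtX, 1)
            rcond, info = dpocon(c, anorm)
            if info == 0 and rcond > 0:
                diagnostics["condition_number"] = float(np.sqrt(1.0 / rcond))
        except np.linalg.LinAlgError:
            warnings.warn("rank-deficient design: returning minimum-norm "
                          "solution", RuntimeWarning, stacklevel=2)
            diagnostics["rank_deficient"] = True
            B, *_ = np.linalg.lstsq(XtX, XtY, rcond=None)
    else:
        raise ValueError(f"unknown solver {solver!r}")

    # residual variance without materialising residuals
    yty = np.einsum("sc,sc->c", Y, Y)
    xty = X.T @ Y
    rss = np.maximum(yty - 2 * np.einsum("pc,pc->c", B, xty)
                     + np.einsum("pc,pq,qc->c", B, XtX, B), 0.0)
    dof = max(n - p, 1)
    resid_var = rss / dof

    return DeconvFit(B.T, design.columns, design.spec, design.spline,
                     eeg.channel_names, design.reference_amplitude,
                     resid_var, diagnostics)


# --------------------------------------------------------------------------
# ERP reconstruction
# --------------------------------------------------------------------------

@dataclass
class ErpWaveform:
    """An ERP over lags, either multichannel or a single (cluster) trace."""

    values: np.ndarray          # (n_channels, n_lags) or (n_lags,)
    lags_ms: np.ndarray
    channel_names: tuple[str, ...] | None = None
    label: str = ""
    baseline_corrected: bool = False

    def copy(self) -> "ErpWaveform":
        return ErpWaveform(self.values.copy(), self.lags_ms.copy(),
                           self.channel_names, self.label,
                           self.baseline_corrected)


def reconstruct_erp(fit_result: DeconvFit, condition: str,
                    amplitude: float | None = None,
                    baseline: tuple[float, float] = (-200.0, 0.0)) -> ErpWaveform:
    """Condition ERP from coefficients, at a given prior-saccade amplitude.

    Environment is the intercept; the landmark conditions add their dummy
    traces. The spline contribution at ``amplitude`` (default: the
    reference amplitude, contributing zero) is added to all conditions.
    The result is baseline-corrected over ``baseline``.
    """
    if condition not in AOI_CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; "
                         f"expected one of {list(AOI_CONDITIONS)}")
    values = fit_result.block("fix_intercept").copy()
    if condition == "LM-Abstract":
        values += fit_result.block("fix_abstract")
    elif condition == "LM-Realistic":
        values += fit_result.block("fix_realistic")
    if amplitude is not None and fit_result.spline is not None:
        w = fit_result.spline.transform(np.array([amplitude]))[0]
        for j, wj in enumerate(w):
            if wj != 0.0:
                values += wj * fit_result.block("sacc_amp_spline", basis=j)
    erp = ErpWaveform(values, fit_result.fix_lags_ms,
                      fit_result.channel_names, label=condition)
    return baseline_correct(erp, baseline)


def baseline_correct(erp: ErpWaveform,
                     window: tuple[float, float] = (-200.0, 0.0)) -> ErpWaveform:
    """Subtract the mean over the baseline window (idempotent)."""
    lo, hi = window
    eps = 1e-9
    if lo < erp.lags_ms[0] - eps or hi > erp.lags_ms[-1] + eps:
        raise ValueError(f"baseline window {window} outside lag axis "
                         f"[{erp.lags_ms[0]}, {erp.lags_ms[-1]}] ms")
    mask = (erp.lags_ms >= lo - eps) & (erp.lags_ms <= hi + eps)
    out = erp.copy()
    if out.values.ndim == 1:
        out.values = out.values - out.values[mask].mean()
    else:
        out.values = out.values - out.values[:, mask].mean(axis=1, keepdims=True)
    out.baseline_corrected = True
    return out


def epoch_average(eeg: ContinuousEEG, onsets: np.ndarray,
                  window_ms: tuple[float, float] = (-200.0, 800.0)) -> ErpWaveform:
    """Naive epoch mean across events (no overlap correction).

    Events whose window extends beyond the recording are skipped. Serves as
    the classical-averaging comparison for the deconvolution estimates.
    """
    lo = int(round(window_ms[0] / 1000.0 * eeg.rate))
    hi = int(round(window_ms[1] / 1000.0 * eeg.rate))
    lags = np.arange(lo, hi + 1)
    acc = np.zeros((eeg.n_channels, len(lags)))
    count = 0
    for onset in np.asarray(onsets, dtype=int):
        if onset + lo < 0 or onset + hi >= eeg.n_samples:
            continue
        acc += eeg.data[:, onset + lo:onset + hi + 1]
        count += 1
    if count == 0:
        raise ValueError("no event fits entirely within the recording")
    return ErpWaveform(acc / count, lags / eeg.rate * 1000.0, eeg.channel_names,
                       label="epoch_average")


# --------------------------------------------------------------------------
# Persistence
# --------------------------------------------------------------------------

def save_fit(path, fit_result: DeconvFit) -> None:
    """Persist a fit (coefficients + column metadata + spec) to HDF5."""
    import json
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("coef", data=fit_result.coef)
        fh.create_dataset("residual_variance", data=fit_result.residual_variance)
        fh.attrs["channel_names"] = list(fit_result.channel_names)
        fh.attrs["columns"] = fit_result.columns.to_json()
        from dataclasses import asdict
        fh.attrs["spec"] = json.dumps(asdict(fit_result.spec))
        fh.attrs["diagnostics"] = json.dumps(fit_result.diagnostics)
        if fit_result.spline is not None:
            fh.attrs["spline"] = json.dumps(dict(
                knots=fit_result.spline.knots.tolist(),
                degree=fit_result.spline.degree,
                reference=fit_result.spline.reference,
                drop_index=fit_result.spline.drop_index,
                n_basis=fit_result.spline.n_basis))


def load_fit(path) -> DeconvFit:
    import io
    import json
    import h5py

    with h5py.File(path, "r") as fh:
        coef = fh["coef"][...]
        resid = fh["residual_variance"][...]
        names = tuple(fh.attrs["channel_names"])
        columns = pd.read_json(io.StringIO(fh.attrs["columns"]))
        s = json.loads(fh.attrs["spec"])
        for key in ("fix_window_ms", "step_window_ms", "sacc_window_ms"):
            s[key] = tuple(s[key])
        spec = DeconvSpec(**s)
        spline = None
        if "spline" in fh.attrs:
            sj = json.loads(fh.attrs["spline"])
            spline = SplineBasis(np.array(sj["knots"]), sj["degree"],
                                 sj["reference"], sj["drop_index"], sj["n_basis"])
        diagnostics = json.loads(fh.attrs["diagnostics"])
    ref = spline.reference if spline is not None else None
    return DeconvFit(coef, columns, spec, spline, names, ref, resid, diagnostics)
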
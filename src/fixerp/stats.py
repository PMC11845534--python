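"""Mixed-effects models on component peaks and Tukey pairwise follow-ups.

The model is ``response ~ AOI * gender + (1 | subject)`` fit by REML, with
AOI treatment-coded against the Environment baseline and gender sum-coded
(+1 female / -1 male, recorded in the output metadata so coefficient signs
stay interpretable). t-tests use containment degrees of freedom — the
exact split-plot df for this design: between-subject terms (intercept,
gender) are tested against subjects (``n_subjects - q_between``),
within-subject terms (AOI and interactions) against the within-subject
error (``n_obs - n_subjects - q_within``). Satterthwaite-type
approximations are not available in the backing library; for balanced
random-intercept data the containment df coincide with the exact ANOVA df.
Pairwise condition contrasts within each gender use estimated marginal
means with Tukey adjustment over the family of three comparisons
(studentized-range distribution) at the within-subject df.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import AOI_CONDITIONS

__all__ = [
    "GENDER_CODE",
    "LmmResult",
    "build_model_frame",
    "fit_lmm",
    "pairwise_by_gender",
    "simulate_peak_table",
]

#: Sum-coding orientation for gender.
GENDER_CODE = {"female": 1.0, "male": -1.0}

FIXED_TERMS = ("Intercept", "LM-Abstract", "LM-Realistic", "gender",
               "LM-Abstract:gender", "LM-Realistic:gender")

#: Terms varying between subjects only; the rest vary within subject.
BETWEEN_TERMS = ("Intercept", "gender")


def build_model_frame(peaks: pd.DataFrame,
                      response: str = "amplitude") -> pd.DataFrame:
    """Design frame for the mixed model from a peak table.

    Expects columns ``subject, gender, condition, <response>`` and
    optionally ``found`` (False rows are excluded — missing peaks never
    enter with imputed values). Raises if any subject lacks a gender label.
    """
    df = peaks.copy()
    if "found" in df.columns:
        df = df[df["found"].astype(bool)]
    df = df[np.isfinite(df[response].to_numpy(float))]
    bad = ~df["gender"].isin(GENDER_CODE)
    if bad.any():
        missing = sorted(df.loc[bad, "subject"].unique())
        raise ValueError(f"subjects with unknown gender: {missing}")
    d_abs = (df["condition"] == "LM-Abstract").astype(float)
    d_real = (df["condition"] == "LM-Realistic").astype(float)
    g = df["gender"].map(GENDER_CODE).astype(float)
    return pd.DataFrame({
        "response": df[response].to_numpy(float),
        "LM-Abstract": d_abs.to_numpy(),
        "LM-Realistic": d_real.to_numpy(),
        "gender": g.to_numpy(),
        "LM-Abstract:gender": (d_abs * g).to_numpy(),
        "LM-Realistic:gender": (d_real * g).to_numpy(),
        "subject": df["subject"].to_numpy(),
    })


@dataclass
class LmmResult:
    """Fixed-effect table plus variance components of one REML fit."""

    terms: pd.DataFrame         # term, beta, se, t, df, p
    re_variance: float
    residual_variance: float
    df_within: float            # containment df for within-subject terms
    df_between: float
    converged: bool
    n_obs: int
    n_subjects: int
    cov_fixed: np.ndarray = field(repr=False, default=None)
    diagnostics: dict = field(default_factory=dict)

    def term(self, name: str) -> pd.Series:
        row = self.terms[self.terms["term"] == name]
        if row.empty:
            raise KeyError(f"no term {name!r}")
        return row.iloc[0]


def fit_lmm(frame: pd.DataFrame) -> LmmResult:
    """REML fit of ``response ~ AOI*gender + (1 | subject)``.

    Non-convergence is flagged in the result (with optimizer diagnostics),
    never silent. Degenerate input (a single condition or subject) raises.
    """
    import statsmodels.api as sm

    if frame["subject"].nunique() < 2:
        raise ValueError("mixed model needs at least 2 subjects")
    n_cond = int((frame[["LM-Abstract", "LM-Realistic"]].sum(axis=1) == 0).any()) \
        + int(frame["LM-Abstract"].any()) + int(frame["LM-Realistic"].any())
    if n_cond < 2:
        raise ValueError("mixed model needs at least 2 observed conditions")

    exog = np.column_stack([
        np.ones(len(frame)),
        frame["LM-Abstract"], frame["LM-Realistic"], frame["gender"],
        frame["LM-Abstract:gender"], frame["LM-Realistic:gender"],
    ])
    model = sm.regression.mixed_linear_model.MixedLM(
        frame["response"].to_numpy(), exog, groups=frame["subject"].to_numpy())
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            result = model.fit(reml=True)
        except np.linalg.LinAlgError:
            result = model.fit(reml=True, method="powell")
    converged = bool(getattr(result, "converged", True))
    messages = [str(w.message) for w in caught]

    beta = np.asarray(result.fe_params)
    se = np.asarray(result.bse_fe)
    t = beta / se
    n_obs = len(frame)
    n_sub = int(frame["subject"].nunique())
    q_between = len(BETWEEN_TERMS)
    q_within = len(FIXED_TERMS) - q_between
    # containment df: between-subject terms against subjects, within-subject
    # terms against the within-subject error stratum (exact for the
    # balanced split-plot layout)
    df_between = float(max(n_sub - q_between, 1))
    df_within = float(max(n_obs - n_sub - q_within, 1))
    df = np.array([df_between if term in BETWEEN_TERMS else df_within
                   for term in FIXED_TERMS])
    p = 2 * sps.t.sf(np.abs(t), df)
    terms = pd.DataFrame({"term": FIXED_TERMS, "beta": beta, "se": se,
                          "t": t, "df": df, "p": p})
    cov_fixed = np.asarray(result.cov_params())[:len(beta), :len(beta)]
    return LmmResult(
        terms=terms,
        re_variance=float(np.asarray(result.cov_re).ravel()[0]),
        residual_variance=float(result.scale),
        df_within=df_within,
        df_between=df_between,
        converged=converged,
        n_obs=n_obs,
        n_subjects=n_sub,
        cov_fixed=cov_fixed,
        diagnostics={"warnings": messages, "method": "reml",
                     "df_method": "containment"},
    )


def _emm_row(condition: str, gender_code: float) -> np.ndarray:
    """Fixed-effect contrast vector of one cell's estimated marginal mean."""
    d_abs = 1.0 if condition == "LM-Abstract" else 0.0
    d_real = 1.0 if condition == "LM-Realistic" else 0.0
    return np.array([1.0, d_abs, d_real, gender_code,
                     d_abs * gender_code, d_real * gender_code])


def pairwise_by_gender(result: LmmResult) -> pd.DataFrame:
    """All pairwise AOI contrasts within each gender, Tukey-adjusted.

    Marginal means come from the fixed-effect estimates; each gender's
    family of three comparisons is corrected with the studentized-range
    distribution (k = 3) at the model's within-subject df (condition
    contrasts are within-subject).
    """
    if not result.converged:
        raise ValueError("model did not converge; pairwise comparisons "
                         "would be unreliable")
    beta = result.terms["beta"].to_numpy()
    rows = []
    k = len(AOI_CONDITIONS)
    for gender, code in GENDER_CODE.items():
        for c1, c2 in itertools.combinations(AOI_CONDITIONS, 2):
            L = _emm_row(c1, code) - _emm_row(c2, code)
            est = float(L @ beta)
            se = float(np.sqrt(L @ result.cov_fixed @ L))
            t = est / se
            p_raw = float(2 * sps.t.sf(abs(t), result.df_within))
            p_tukey = float(sps.studentized_range.sf(
                abs(t) * np.sqrt(2.0), k, result.df_within))
            rows.append(dict(gender=gender, contrast=f"{c1} - {c2}",
                             estimate=est, se=se, t=t,
                             p_raw=p_raw, p_tukey=min(p_tukey, 1.0)))
    return pd.DataFrame(rows)


def simulate_peak_table(n_subjects: int,
                        effects: dict[str, float] | None = None,
                        re_sd: float = 0.5, resid_sd: float = 0.5,
                        rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Simulate a balanced subject x condition peak table.

    ``effects`` maps fixed-term names (see :data:`FIXED_TERMS`) to true
    values; unlisted terms are zero. Used for calibration (null) and
    parameter-recovery simulations of the mixed model in isolation.
    """
    rng = rng or np.random.default_rng()
    effects = effects or {}
    rows = []
    for i in range(n_subjects):
        subject = f"sim-{i + 1:02d}"
        gender = "female" if i % 2 == 0 else "male"
        g = GENDER_CODE[gender]
        u = rng.normal(0, re_sd)
        for cond in AOI_CONDITIONS:
            x = _emm_row(cond, g)
            mu = sum(effects.get(term, 0.0) * xi
                     for term, xi in zip(FIXED_TERMS, x))
            rows.append(dict(subject=subject, gender=gender, condition=cond,
                             amplitude=mu + u + rng.normal(0, resid_sd),
                             found=True))
    return pd.DataFrame(rows)
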
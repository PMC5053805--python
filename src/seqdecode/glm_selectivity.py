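"""Poisson GLMs of binned spiking with position/locomotion and task predictors.

Spike counts in 10 ms bins within each trial's analysis epoch (sample press
to choice press by default) are modeled with a Poisson GLM (log link).  The
predictors are:

* 9 binary head-position tiles (3 x 3 grid over the 9.5 x 12 in chamber),
* 8 binary head-direction sectors (45 degrees each, half-open),
* 3 velocity terms (vx, vy, speed; boxcar-smoothed finite differences),
* 10 binary delay-time indicators (1 s bins from delay onset, zero outside
  the trial's own delay period),
* 1 sample-side indicator, and
* 10 time x sample interaction terms,

41 predictors in total.  Nested likelihood-ratio tests compare a reduced
model with position/locomotion predictors only against a full model that
adds the task block: the time indicators alone (time coding, 10 df) or time
+ sample + interactions (sample-memory coding, 21 df).  One indicator per
categorical group is dropped as the reference level, so the intercepted
design stays full rank; never-active indicator columns are dropped from
both models alike and do not change the test's degrees of freedom logic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .session_model import Session

__all__ = [
    "DesignMatrix",
    "GlmFit",
    "build_design",
    "bin_response",
    "fit_poisson_glm",
    "lr_test",
    "glm_unit_tests",
    "time_coding_test",
    "sample_coding_test",
]

log = logging.getLogger(__name__)

GLM_BIN_S = 0.01
N_TIME_BINS = 10

POSITION_COLS = [f"pos_{i}" for i in range(9)]
DIRECTION_COLS = [f"dir_{i}" for i in range(8)]
VELOCITY_COLS = ["vx", "vy", "speed"]
TIME_COLS = [f"time_{i}" for i in range(N_TIME_BINS)]
SAMPLE_COL = "sample"
INTERACTION_COLS = [f"time_{i}_x_sample" for i in range(N_TIME_BINS)]

@dataclass
class DesignMatrix:
    """Predictors on the 10 ms analysis grid, plus per-row bookkeeping."""

    X: pd.DataFrame
    bin_start_s: np.ndarray
    trial_index: np.ndarray
    bin_s: float = GLM_BIN_S

    @property
    def n_rows(self) -> int:
        return len(self.X)


@dataclass
class GlmFit:
    coefficients: pd.Series
    log_likelihood: float
    n_params: int
    converged: bool
    n_rows: int = 0


def build_design(
    session: Session,
    epochs: np.ndarray | None = None,
    bin_s: float = GLM_BIN_S,
    boxcar_frames: int = 3,
) -> DesignMatrix:
    """Build the predictor matrix for the session's analysis epochs.

    Default epochs run from each trial's sample press to its choice press
    (trials lacking either event are skipped); the delay-time indicators are
    active only inside each trial's own delay period.
    """
    df = session.trials.df
    rows_t, rows_trial, rows_d0, rows_delay, rows_sample = [], [], [], [], []
    if epochs is None:
        for _, tr in df.iterrows():
            t0, t1 = tr["t_sample_press"], tr["t_choice_press"]
            if not (np.isfinite(t0) and np.isfinite(t1)):
                continue
            starts = np.arange(t0, t1 - bin_s / 2, bin_s)
            rows_t.append(starts)
            rows_trial.append(np.full(starts.size, int(tr["trial_index"])))
            rows_d0.append(np.full(starts.size, t0))
            rows_delay.append(np.full(starts.size, float(tr["delay_s"])))
            rows_sample.append(np.full(starts.size, 1.0 if tr["sample_side"] == "right" else 0.0))
    else:
        for t0, t1 in epochs:
            starts = np.arange(t0, t1 - bin_s / 2, bin_s)
            rows_t.append(starts)
            rows_trial.append(np.full(starts.size, -1))
            rows_d0.append(np.full(starts.size, np.nan))
            rows_delay.append(np.zeros(starts.size))
            rows_sample.append(np.zeros(starts.size))
    if not rows_t:
        raise ValueError("no usable analysis epochs")
    t = np.concatenate(rows_t)
    trial_index = np.concatenate(rows_trial)
    d0 = np.concatenate(rows_d0)
    delay = np.concatenate(rows_delay)
    sample = np.concatenate(rows_sample)
    centers = t + bin_s / 2

    track = session.tracking
    w = np.ones(boxcar_frames) / boxcar_frames
    vx = np.convolve(track.vx, w, mode="same")
    vy = np.convolve(track.vy, w, mode="same")
    x = np.interp(centers, track.t_s, track.x_in)
    y = np.interp(centers, track.t_s, track.y_in)
    # nearest-frame heading: linear interpolation would corrupt 0/360 wraps
    nearest = np.clip(
        np.round((centers - track.t_s[0]) / track.dt).astype(int), 0, track.t_s.size - 1
    )
    hd = track.heading_deg[nearest]
    vxi = np.interp(centers, track.t_s, vx)
    vyi = np.interp(centers, track.t_s, vy)
    spi = np.hypot(vxi, vyi)

    cw, ch = session.chamber["width_in"], session.chamber["height_in"]
    tx = np.clip((x / (cw / 3)).astype(int), 0, 2)
    ty = np.clip((y / (ch / 3)).astype(int), 0, 2)
    tile = ty * 3 + tx
    sector = np.clip((hd / 45.0).astype(int), 0, 7)

    cols = {}
    for i, c in enumerate(POSITION_COLS):
        cols[c] = (tile == i).astype(float)
    for i, c in enumerate(DIRECTION_COLS):
        cols[c] = (sector == i).astype(float)
    cols["vx"], cols["vy"], cols["speed"] = vxi, vyi, spi
    t_rel = centers - d0
    in_delay = np.isfinite(d0) & (t_rel >= 0) & (t_rel < delay)
    for i, c in enumerate(TIME_COLS):
        cols[c] = (in_delay & (t_rel >= i) & (t_rel < i + 1)).astype(float)
    cols[SAMPLE_COL] = sample
    for i, c in enumerate(INTERACTION_COLS):
        cols[c] = cols[TIME_COLS[i]] * sample
    X = pd.DataFrame(cols)
    return DesignMatrix(X, t, trial_index, bin_s)


def bin_response(design: DesignMatrix, spike_times: np.ndarray) -> np.ndarray:
    """Spike counts in each design row's 10 ms bin."""
    t = np.asarray(spike_times, float)
    lo = np.searchsorted(t, design.bin_start_s)
    hi = np.searchsorted(t, design.bin_start_s + design.bin_s)
    return (hi - lo).astype(float)


def fit_poisson_glm(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    tol: float = 1e-8,
    maxiter: int = 200,
    start: pd.Series | None = None,
) -> GlmFit:
    """Maximum-likelihood Poisson GLM with log link (intercept added here).

    ``start`` warm-starts the IRLS iterations from a (typically nested)
    fit's coefficients, matched by column name; missing columns start at 0.
    """
    Xd = pd.DataFrame(X)
    zero = [c for c in Xd.columns if not np.any(Xd[c].to_numpy())]
    if zero:
        raise ValueError(f"all-zero predictor columns: {zero}")
    exog = sm.add_constant(Xd, has_constant="add")
    yv = np.asarray(y, float)
    model = sm.GLM(yv, exog, family=sm.families.Poisson())
    kwargs = {}
    if start is not None:
        kwargs["start_params"] = np.array([start.get(c, 0.0) for c in exog.columns])
    try:
        res = model.fit(maxiter=maxiter, tol=tol, **kwargs)
        converged = bool(getattr(res, "converged", True))
        llf = float(res.llf)
        if not np.isfinite(llf) or llf > 1e-12:  # Poisson llf <= 0 up to rounding
            converged, llf = False, np.nan
        return GlmFit(res.params, llf, int(exog.shape[1]), converged, len(Xd))
    except Exception as exc:  # separation / numerical failure
        log.warning("GLM fit failed: %s", exc)
        return GlmFit(pd.Series(dtype=float), np.nan, int(exog.shape[1]), False, len(Xd))


def lr_test(reduced: GlmFit, full: GlmFit) -> tuple[float, int, float]:
    """Nested likelihood-ratio test: 2 * delta logL ~ chi-square(delta df)."""
    if full.n_rows != reduced.n_rows:
        raise ValueError("nested models must be fit on the same rows")
    df = full.n_params - reduced.n_params
    if df < 0:
        raise ValueError("full model has fewer parameters than the reduced model")
    stat = max(0.0, 2.0 * (full.log_likelihood - reduced.log_likelihood))
    p = float(stats.chi2.sf(stat, df)) if df > 0 else 1.0
    return float(stat), int(df), p


def _active(X: pd.DataFrame, names: list[str]) -> list[str]:
    return [c for c in names if c in X.columns and np.any(X[c].to_numpy())]


def _categorical_block(X: pd.DataFrame, names: list[str]) -> list[str]:
    """Active indicator columns minus the first one (the reference level).

    One-hot groups need a reference dropped to stay independent of the
    intercept; dropping the first *active* level keeps the design full rank
    even when some levels never occur.
    """
    return _active(X, names)[1:]


def _nested_test(
    design: DesignMatrix, response: np.ndarray, task_cols: list[str]
) -> tuple[float, int, float, bool]:
    base_cols = (
        _categorical_block(design.X, POSITION_COLS)
        + _categorical_block(design.X, DIRECTION_COLS)
        + _active(design.X, VELOCITY_COLS)
    )
    task = _active(design.X, task_cols)
    reduced = fit_poisson_glm(design.X[base_cols], response)
    full = fit_poisson_glm(design.X[base_cols + task], response)
    if not (reduced.converged and full.converged):
        return np.nan, len(task), np.nan, False
    stat, df, p = lr_test(reduced, full)
    return stat, df, p, True


def glm_unit_tests(design: DesignMatrix, response: np.ndarray) -> dict:
    """Both nested tests for one unit, sharing the reduced (position-only) fit.

    Returns ``{"p_time", "p_sample", "df_time", "df_sample", "converged"}``
    with NaN p-values when a fit fails.
    """
    base_cols = (
        _categorical_block(design.X, POSITION_COLS)
        + _categorical_block(design.X, DIRECTION_COLS)
        + _active(design.X, VELOCITY_COLS)
    )
    reduced = fit_poisson_glm(design.X[base_cols], response)
    out = {"p_time": np.nan, "p_sample": np.nan, "df_time": 0, "df_sample": 0,
           "converged": reduced.converged}
    if not reduced.converged:
        return out
    for key, cols in (
        ("time", TIME_COLS),
        ("sample", TIME_COLS + [SAMPLE_COL] + INTERACTION_COLS),
    ):
        task = _active(design.X, cols)
        full = fit_poisson_glm(design.X[base_cols + task], response, start=reduced.coefficients)
        if full.converged:
            _, df, p = lr_test(reduced, full)
            out[f"p_{key}"], out[f"df_{key}"] = p, df
        else:
            out["converged"] = False
    return out


def time_coding_test(
    session: Session,
    unit_id: str,
    design: DesignMatrix | None = None,
    response: np.ndarray | None = None,
) -> float:
    """Does delay time predict spiking beyond position and locomotion?

    Likelihood-ratio p for adding the 10 delay-time indicators to the
    position/direction/velocity model.  NaN when either fit fails.
    """
    if design is None:
        design = build_design(session)
    if response is None:
        response = bin_response(design, session.unit(unit_id).spike_times_s)
    return _nested_test(design, response, TIME_COLS)[2]


def sample_coding_test(
    session: Session,
    unit_id: str,
    design: DesignMatrix | None = None,
    response: np.ndarray | None = None,
) -> float:
    """Does the task block (time + sample + interaction) predict spiking
    beyond position and locomotion?  Likelihood-ratio p, 21 df nominally."""
    if design is None:
        design = build_design(session)
    if response is None:
        response = bin_response(design, session.unit(unit_id).spike_times_s)
    return _nested_test(design, response, TIME_COLS + [SAMPLE_COL] + INTERACTION_COLS)[2]
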
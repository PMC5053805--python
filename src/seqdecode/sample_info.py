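"""Time-varying mutual information between spiking and the sample stimulus.

The model: within a 500 ms window split into k = 10 bins of 50 ms, a unit's
spike counts are independent Poisson with side-conditional rates
``lambda_left(t)``, ``lambda_right(t)`` estimated from smoothed condition
PSTHs.  For one observed count sequence s = (s_1 .. s_k) and its sample side
x, the pointwise mutual information is::

    log2[ P(s | x) / ( 1/2 P(s | left) + 1/2 P(s | right) ) ]

with P(s | x) = prod_i Poisson(s_i; lambda_x(bin_i) * 0.05 s).  Averaging
the pointwise value over Monte-Carlo draws (x uniform, s ~ model) estimates
the mutual information of the fitted model, bounded by 1 bit for a binary
equiprobable stimulus.  Significance of an information peak uses a
trial-label shuffle: side labels are permuted across trials, the condition
rates refitted, the trace recomputed, and the observed peak compared to the
99th percentile of the null peaks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from itertools import product
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.special import gammaln, logsumexp

from .rate_maps import DEFAULT_BIN_S, DEFAULT_SIGMA_S, binned_counts, event_times, gaussian_kernel
from .session_model import Session

__all__ = [
    "InfoTrace",
    "RATE_FLOOR_HZ",
    "choice_sides",
    "condition_rate_models",
    "pointwise_mi",
    "mi_exact",
    "mi_at_time",
    "info_trace",
    "shuffle_significance",
    "press_info",
    "press_context_dispersion",
    "press_dispersion_analysis",
    "info_vs_rate_peak_comparison",
]

log = logging.getLogger(__name__)

#: Rate floor (Hz) inside Poisson likelihoods, so a spike under a fitted rate
#: of exactly 0 has finite log-probability.
RATE_FLOOR_HZ = 0.01
WINDOW_S = 0.5
N_MC = 500
N_SHUFFLES = 200
LOG2 = np.log(2.0)


@dataclass
class InfoTrace:
    """Sliding-window sample information (bits) of one unit."""

    unit_id: str
    window_centers_s: np.ndarray
    mi_bits: np.ndarray
    mc_se: np.ndarray
    params: dict = field(default_factory=dict)
    null_peak_99: float | None = None
    significant: bool | None = None
    p: float | None = None

    @property
    def peak_time_s(self) -> float:
        return float(self.window_centers_s[int(np.argmax(self.mi_bits))])

    @property
    def peak_bits(self) -> float:
        return float(np.max(self.mi_bits))


def choice_sides(trials_df) -> np.ndarray:
    """Chosen lever per trial (non-match of the sample when correct)."""
    opposite = {"left": "right", "right": "left"}
    out = []
    for _, row in trials_df.iterrows():
        if row["outcome"] == "correct":
            out.append(opposite[row["sample_side"]])
        elif row["outcome"] == "error":
            out.append(row["sample_side"])
        else:
            out.append(None)
    return np.array(out, dtype=object)


# ---------------------------------------------------------------------------
# Condition rate models
# ---------------------------------------------------------------------------

class UnitInfoModel:
    """Cached per-trial spike counts of one unit on the model time grid.

    Holds everything needed to (re)fit side-conditional rate models under
    arbitrary label assignments — the workhorse behind both the observed
    information trace and its label-shuffle null.
    """

    def __init__(
        self,
        spike_times: np.ndarray,
        events: np.ndarray,
        labels: np.ndarray,
        window: tuple,
        bin_s: float = DEFAULT_BIN_S,
        sigma_s: float = DEFAULT_SIGMA_S,
        floor_hz: float = RATE_FLOOR_HZ,
    ):
        keep = np.isfinite(events)
        self.events = np.asarray(events, float)[keep]
        self.labels = np.asarray(labels)[keep]
        if (self.labels == "left").sum() < 2 or (self.labels == "right").sum() < 2:
            raise ValueError("need at least 2 trials per side to fit rate models")
        self.window = tuple(window)
        self.bin_s = float(bin_s)
        self.sigma_s = float(sigma_s)
        self.floor_hz = float(floor_hz)
        self.counts = binned_counts(spike_times, self.events, window, bin_s)
        self.kernel = gaussian_kernel(sigma_s, bin_s)
        self._ones = np.convolve(np.ones(self.counts.shape[1]), self.kernel, mode="same")
        self.bin_centers = window[0] + (np.arange(self.counts.shape[1]) + 0.5) * bin_s

    def rates(self, labels: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Smoothed (lambda_left, lambda_right) in Hz under ``labels``."""
        labels = self.labels if labels is None else labels
        out = []
        for side in ("left", "right"):
            m = self.counts[labels == side].mean(axis=0) / self.bin_s
            out.append(np.convolve(m, self.kernel, mode="same") / self._ones)
        return out[0], out[1]

    def window_slice(self, t_center: float, window_s: float = WINDOW_S) -> slice:
        sel = np.flatnonzero(
            (self.bin_centers > t_center - window_s / 2)
            & (self.bin_centers < t_center + window_s / 2)
        )
        if sel.size == 0:
            raise ValueError(f"window at {t_center} s not covered by the rate model")
        return slice(sel[0], sel[-1] + 1)


def condition_rate_models(
    session: Session,
    unit_id: str,
    align_event: str = "sample_press",
    delays=(10.0,),
    window: tuple = (-1.0, 11.0),
    bin_s: float = DEFAULT_BIN_S,
    sigma_s: float = DEFAULT_SIGMA_S,
    correct_only: bool = True,
    floor_hz: float = RATE_FLOOR_HZ,
) -> UnitInfoModel:
    """Fit left/right condition rate models for one unit (smoothed PSTHs)."""
    outcomes = ("correct",) if correct_only else ("correct", "error")
    df = session.trials.select(outcome=outcomes, delay_s=tuple(np.atleast_1d(delays)))
    events = event_times(session, align_event, df)
    return UnitInfoModel(
        session.unit(unit_id).spike_times_s,
        events,
        df["sample_side"].to_numpy(),
        window,
        bin_s,
        sigma_s,
        floor_hz,
    )


# ---------------------------------------------------------------------------
# Mutual information
# ---------------------------------------------------------------------------

def pointwise_mi(
    counts: np.ndarray,
    lam_left: np.ndarray,
    lam_right: np.ndarray,
    x: str,
    dt: float = DEFAULT_BIN_S,
    floor_hz: float = RATE_FLOOR_HZ,
) -> float:
    """Pointwise MI (bits) of one count sequence with its sample side ``x``."""
    counts = np.asarray(counts)
    if np.any(counts < 0):
        raise ValueError("spike counts must be non-negative")
    mu = np.maximum(np.vstack([lam_left, lam_right]), floor_hz) * dt
    if np.array_equal(mu[0], mu[1]):
        return 0.0  # identical models carry no information, exactly
    ll = counts @ np.log(mu).T - mu.sum(axis=1)  # log P(s|side) + const
    ll_x = ll[0] if x == "left" else ll[1]
    return float((ll_x - logsumexp(ll + np.log(0.5))) / LOG2)


def _mc_mi(
    lam_left: np.ndarray,
    lam_right: np.ndarray,
    n_mc: int,
    rng: np.random.Generator,
    dt: float = DEFAULT_BIN_S,
    floor_hz: float = RATE_FLOOR_HZ,
    batch: int = 50,
) -> tuple[float, float]:
    """Monte-Carlo MI estimate and its standard error (batches of ``batch``).

    Count sequences are simulated from the fitted model (side drawn uniformly,
    counts Poisson under that side's rates).  For each simulated sequence the
    pointwise MI is averaged over the posterior of the side given the counts
    (conditional Monte Carlo), which has the same expectation as scoring the
    sampled side but smaller variance.
    """
    mu = np.maximum(np.vstack([lam_left, lam_right]), floor_hz) * dt  # (2, k)
    x = rng.integers(0, 2, n_mc)
    counts = rng.poisson(mu[x])
    log_mu = np.log(mu)
    ll = counts @ log_mu.T - mu.sum(axis=1)  # (n_mc, 2), factorials cancel
    log_mix = logsumexp(ll + np.log(0.5), axis=1)
    posterior = np.exp(ll + np.log(0.5) - log_mix[:, None])  # P(side | s)
    pmi = (posterior * (ll - log_mix[:, None])).sum(axis=1) / LOG2
    n_full = (n_mc // batch) * batch
    if n_full >= 2 * batch:
        means = pmi[:n_full].reshape(-1, batch).mean(axis=1)
        se = float(means.std(ddof=1) / np.sqrt(means.size))
    else:
        se = float(pmi.std(ddof=1) / np.sqrt(n_mc))
    return float(pmi.mean()), se


def mi_exact(
    lam_left: np.ndarray,
    lam_right: np.ndarray,
    dt: float = DEFAULT_BIN_S,
    floor_hz: float = RATE_FLOOR_HZ,
    max_count: int = 50,
) -> float:
    """Brute-force MI (bits) by summing the discrete joint over count grids.

    Only feasible for short windows (k <= ~4 bins); serves as the
    independent oracle for the Monte-Carlo estimator.
    """
    mu = np.maximum(np.vstack([lam_left, lam_right]), floor_hz) * dt
    k = mu.shape[1]
    if (max_count + 1) ** k > 2_000_000:
        raise ValueError("count grid too large for exact summation")
    grid = np.array(list(product(range(max_count + 1), repeat=k)))
    log_p = grid @ np.log(mu).T - mu.sum(axis=1) - gammaln(grid + 1).sum(axis=1)[:, None]
    p = np.exp(log_p)  # (grid, 2) = P(s | side)
    mix = 0.5 * p.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = 0.5 * p * (np.log(p) - np.log(mix)[:, None]) / LOG2
    return float(np.nansum(terms))


def mi_at_time(
    model: UnitInfoModel,
    t_center: float,
    n_mc: int = N_MC,
    rng: np.random.Generator | None = None,
    window_s: float = WINDOW_S,
    labels: np.ndarray | None = None,
) -> tuple[float, float]:
    """Monte-Carlo sample information (bits) in the 500 ms window at ``t_center``."""
    rng = np.random.default_rng() if rng is None else rng
    lam_l, lam_r = model.rates(labels)
    sl = model.window_slice(t_center, window_s)
    return _mc_mi(lam_l[sl], lam_r[sl], n_mc, rng, model.bin_s, model.floor_hz)


def _trace(
    model: UnitInfoModel,
    centers: np.ndarray,
    n_mc: int,
    rng: np.random.Generator,
    window_s: float,
    labels: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    lam_l, lam_r = model.rates(labels)
    mi = np.empty(centers.size)
    se = np.empty(centers.size)
    for i, c in enumerate(centers):
        sl = model.window_slice(c, window_s)
        mi[i], se[i] = _mc_mi(lam_l[sl], lam_r[sl], n_mc, rng, model.bin_s, model.floor_hz)
    return mi, se


def trace_centers(span: tuple, window_s: float = WINDOW_S, stride_s: float = 0.05) -> np.ndarray:
    """Window centers of a sliding window covering ``span``: length
    floor((span - window)/stride) + 1."""
    t0, t1 = span
    n = int(np.floor((t1 - t0 - window_s) / stride_s + 1e-9)) + 1
    if n < 1:
        raise ValueError("span shorter than the sliding window")
    return t0 + window_s / 2 + stride_s * np.arange(n)


def info_trace(
    session: Session,
    unit_id: str,
    align_event: str = "sample_press",
    delays=(10.0,),
    span: tuple | None = None,
    stride_s: float = 0.05,
    window_s: float = WINDOW_S,
    n_mc: int = N_MC,
    rng: np.random.Generator | None = None,
    model: UnitInfoModel | None = None,
) -> InfoTrace:
    """Sliding-window sample information across the delay period.

    The default span is the delay period itself ([0, delay]), so the peak is
    taken over the delay, matching the sequence/peak conventions.
    """
    rng = np.random.default_rng() if rng is None else rng
    delay = float(np.max(np.atleast_1d(delays)))
    span = (0.0, delay) if span is None else span
    if model is None:
        model = condition_rate_models(
            session, unit_id, align_event, delays, window=(span[0] - 1.0, span[1] + 1.0)
        )
    centers = trace_centers(span, window_s, stride_s)
    mi, se = _trace(model, centers, n_mc, rng, window_s)
    return InfoTrace(
        unit_id,
        centers,
        mi,
        se,
        params={
            "window_s": window_s,
            "bin_s": model.bin_s,
            "k": int(round(window_s / model.bin_s)),
            "n_mc": n_mc,
            "align_event": align_event,
            "delays": tuple(np.atleast_1d(delays)),
            "span": tuple(span),
            "stride_s": stride_s,
        },
    )


def shuffle_significance(
    session: Session,
    unit_id: str,
    n_shuffles: int = N_SHUFFLES,
    rng: np.random.Generator | None = None,
    trace: InfoTrace | None = None,
    model: UnitInfoModel | None = None,
    **trace_kwargs,
) -> InfoTrace:
    """Label-shuffle significance of a unit's information peak.

    Each shuffle permutes the left/right labels globally across trials
    (preserving the side counts), refits the condition rates with the same
    smoothing pipeline, recomputes the trace, and records its peak over the
    delay period.  The unit is significant when the observed peak exceeds
    the 99th percentile of the null peaks.
    """
    if n_shuffles < 100:
        log.warning("n_shuffles=%d is below the documented minimum of 100", n_shuffles)
    rng = np.random.default_rng() if rng is None else rng
    if trace is None:
        trace = info_trace(session, unit_id, rng=rng, model=model, **trace_kwargs)
    if model is None:
        span = trace.params["span"]
        model = condition_rate_models(
            session,
            unit_id,
            trace.params["align_event"],
            trace.params["delays"],
            window=(span[0] - 1.0, span[1] + 1.0),
        )
    centers = trace.window_centers_s
    n_mc = trace.params["n_mc"]
    window_s = trace.params["window_s"]
    null_peaks = np.empty(n_shuffles)
    for j in range(n_shuffles):
        labels = rng.permutation(model.labels)
        mi, _ = _trace(model, centers, n_mc, rng, window_s, labels)
        null_peaks[j] = mi.max()
    # order-statistic ("higher") percentile keeps the nominal level at <= 1%
    thr = float(np.percentile(null_peaks, 99, method="higher"))
    peak = trace.peak_bits
    p = (1.0 + np.sum(null_peaks >= peak)) / (1.0 + n_shuffles)
    return replace(trace, null_peak_99=thr, significant=bool(peak > thr), p=float(p))


# ---------------------------------------------------------------------------
# Lever-press information
# ---------------------------------------------------------------------------

def _press_events(session: Session, press_type: str):
    df = session.trials.df
    if press_type == "sample":
        events = df["t_sample_press"].to_numpy(float)
        labels = df["sample_side"].to_numpy(object)
    elif press_type == "choice":
        events = df["t_choice_press"].to_numpy(float)
        labels = choice_sides(df)
    else:
        raise ValueError("press_type must be 'sample' or 'choice'")
    keep = np.isfinite(events) & np.array([l in ("left", "right") for l in labels])
    return events[keep], labels[keep].astype(str)


def press_info(
    session: Session,
    unit_id: str,
    press_type: str,
    n_mc: int = N_MC,
    rng: np.random.Generator | None = None,
    window_s: float = WINDOW_S,
    events: np.ndarray | None = None,
    labels: np.ndarray | None = None,
) -> float:
    """Lever-side information (bits) in one 500 ms window centered at a press."""
    rng = np.random.default_rng() if rng is None else rng
    if events is None or labels is None:
        events, labels = _press_events(session, press_type)
    half = window_s / 2
    model = UnitInfoModel(
        session.unit(unit_id).spike_times_s, events, labels, (-half - 0.5, half + 0.5)
    )
    return mi_at_time(model, 0.0, n_mc, rng, window_s)[0]


def press_context_dispersion(
    diffs_real: np.ndarray, diffs_shuffled: np.ndarray
) -> tuple[float, float]:
    """Two-sample F-test for equal variance of (sample - choice) information,
    real vs press-type-shuffled.  Returns ``(F, p)`` (two-sided)."""
    a, b = np.asarray(diffs_real, float), np.asarray(diffs_shuffled, float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("degenerate dispersion test: both samples have zero variance")
    F = va / max(vb, 1e-300)
    dfa, dfb = a.size - 1, b.size - 1
    p = 2 * min(stats.f.sf(F, dfa, dfb), stats.f.cdf(F, dfa, dfb))
    return float(F), float(min(p, 1.0))


def press_dispersion_analysis(
    session: Session,
    unit_ids: Sequence[str] | None = None,
    n_shuffles: int = 20,
    n_mc: int = N_MC,
    rng: np.random.Generator | None = None,
) -> dict:
    """Do units specialize by press context (sample vs choice)?

    Per unit, sample-press and choice-press information are computed; the
    spread of their difference across units is compared (F-test) with the
    spread obtained after shuffling press-type labels within each unit.
    """
    rng = np.random.default_rng() if rng is None else rng
    unit_ids = session.unit_ids if unit_ids is None else list(unit_ids)
    ev_s, lab_s = _press_events(session, "sample")
    ev_c, lab_c = _press_events(session, "choice")
    real_s, real_c, shuf_diffs = [], [], []
    ev_all = np.concatenate([ev_s, ev_c])
    lab_all = np.concatenate([lab_s, lab_c])
    is_sample = np.r_[np.ones(ev_s.size, bool), np.zeros(ev_c.size, bool)]
    for u in unit_ids:
        real_s.append(press_info(session, u, "sample", n_mc, rng, events=ev_s, labels=lab_s))
        real_c.append(press_info(session, u, "choice", n_mc, rng, events=ev_c, labels=lab_c))
        for _ in range(n_shuffles):
            perm = rng.permutation(is_sample)
            i_s = press_info(session, u, "sample", n_mc, rng,
                             events=ev_all[perm], labels=lab_all[perm])
            i_c = press_info(session, u, "choice", n_mc, rng,
                             events=ev_all[~perm], labels=lab_all[~perm])
            shuf_diffs.append(i_s - i_c)
    diffs = np.array(real_s) - np.array(real_c)
    F, p = press_context_dispersion(diffs, np.array(shuf_diffs))
    return {
        "sample_bits": np.array(real_s),
        "choice_bits": np.array(real_c),
        "diffs_real": diffs,
        "diffs_shuffled": np.array(shuf_diffs),
        "F": F,
        "p": p,
    }


def info_vs_rate_peak_comparison(
    info_peaks: np.ndarray, rate_peaks: np.ndarray
) -> tuple[float, float, float]:
    """Dissociation of information timing from rate timing.

    Returns the Pearson correlation between paired peak times with its
    two-sided p, plus the one-sided Wilcoxon signed-rank p for information
    peaks occurring *earlier* than rate peaks.
    """
    a, b = np.asarray(info_peaks, float), np.asarray(rate_peaks, float)
    if a.size != b.size or a.size < 3:
        raise ValueError("need >= 3 paired peak times")
    r, p_corr = stats.pearsonr(a, b)
    d = a - b
    if np.all(d == 0):
        p_signed = 1.0
    else:
        p_signed = float(stats.wilcoxon(d[d != 0], alternative="less").pvalue)
    return float(r), float(p_corr), p_signed
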
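"""Sequence statistics: ridge-to-background ratios with circular-shift nulls.

A unit participating in a population sequence shows a transient rate peak at
a reproducible time relative to the aligning event.  The ridge-to-background
ratio quantifies this: the mean rate in an 11-bin (1.1 s) window centered at
the unit's peak, divided by the mean rate of all other 0.1 s bins in a wide
(+/-50 s) background window.  Significance comes from a circular-shift null:
spike times are rotated by a random offset modulo the session duration,
which preserves the rate and the inter-spike-interval structure while
destroying event alignment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .rate_maps import binned_counts, event_times
from .session_model import Session, SpikeTrain

__all__ = [
    "RidgeResult",
    "PEAK_PROFILES",
    "ridge_to_background",
    "circular_shift_null",
    "ridge_significance",
    "population_ridge_test",
    "peak_order_correlation",
    "peak_bias_test",
]

log = logging.getLogger(__name__)

RATE_BIN_S = 0.1
RIDGE_BINS = 11
BACKGROUND_WINDOW_S = (-50.0, 50.0)
N_SHIFTS = 1000
MIN_SHIFT_S = 1.0

#: Named peak-search window profiles (seconds relative to the aligning event).
#: ``delay`` expands to [-1, delay + 1]; ``event`` to [-5, +15]; ``delay_only``
#: to [0, delay].
PEAK_PROFILES = ("delay", "event", "delay_only")


def resolve_peak_window(profile: str, delay_s: float = 10.0) -> tuple:
    if profile == "delay":
        return (-1.0, delay_s + 1.0)
    if profile == "event":
        return (-5.0, 15.0)
    if profile == "delay_only":
        return (0.0, delay_s)
    raise ValueError(f"unknown peak profile {profile!r}; choose one of {PEAK_PROFILES}")


@dataclass
class RidgeResult:
    """Observed ridge-to-background ratio with its circular-shift null."""

    ratio: float
    null_ratios: np.ndarray
    p: float
    peak_time_s: float
    params: dict = field(default_factory=dict)


def ridge_to_background(
    rates: np.ndarray,
    bin_centers: np.ndarray,
    peak_search_window: tuple,
    ridge_bins: int = RIDGE_BINS,
    valid: np.ndarray | None = None,
) -> tuple[float, float]:
    """Ridge/background ratio of one rate row on 0.1 s bins.

    Masked (invalid) bins are excluded from both the ridge and the
    background.  Returns ``(ratio, peak_time)``.
    """
    rates = np.asarray(rates, float)
    valid = np.ones(rates.size, bool) if valid is None else np.asarray(valid, bool)
    in_search = (bin_centers >= peak_search_window[0]) & (bin_centers <= peak_search_window[1])
    search = in_search & valid
    if not search.any():
        raise ValueError("no valid bins inside the peak search window")
    masked = np.where(search, rates, -np.inf)
    peak = int(np.argmax(masked))
    half = ridge_bins // 2
    lo, hi = max(0, peak - half), min(rates.size, peak + half + 1)
    ridge_sel = np.zeros(rates.size, bool)
    ridge_sel[lo:hi] = True
    ridge_sel &= valid
    bg_sel = valid & ~ridge_sel
    bg = rates[bg_sel].mean() if bg_sel.any() else 0.0
    if bg <= 0:
        raise ValueError("degenerate background (mean background rate is 0)")
    return float(rates[ridge_sel].mean() / bg), float(bin_centers[peak])


def _rotate(spike_times: np.ndarray, shift: float, duration: float) -> np.ndarray:
    """Circularly shift sorted spike times by ``shift`` modulo ``duration``."""
    cut = np.searchsorted(spike_times, duration - shift)
    return np.concatenate([spike_times[cut:] + shift - duration, spike_times[:cut] + shift])


def circular_shift_null(
    spiketrain: SpikeTrain,
    session: Session,
    analysis: Callable[[SpikeTrain], float],
    n_shifts: int = N_SHIFTS,
    rng: np.random.Generator | None = None,
    min_shift_s: float = MIN_SHIFT_S,
) -> tuple[float, np.ndarray, float]:
    """Generic circular-shift null for any scalar spike-train statistic.

    Shift offsets are uniform over ``[min_shift_s, duration - min_shift_s]``
    (a minimum shift avoids near-identity surrogates).  Returns
    ``(observed, null_values, p)`` with the add-one one-tailed p-value
    ``p = (1 + #{null >= observed}) / (1 + n_shifts)``, which is never 0.
    """
    if n_shifts < 100:
        log.warning("n_shifts=%d is below the documented minimum of 100", n_shifts)
    rng = np.random.default_rng() if rng is None else rng
    duration = session.duration_s
    t = spiketrain.spike_times_s
    observed = float(analysis(spiketrain))
    null = np.empty(n_shifts)
    for i in range(n_shifts):
        shift = rng.uniform(min_shift_s, duration - min_shift_s)
        null[i] = analysis(SpikeTrain(spiketrain.unit_id, _rotate(t, shift, duration)))
    p = (1.0 + np.sum(null >= observed)) / (1.0 + n_shifts)
    return observed, null, float(p)


def _psth(spikes: np.ndarray, events: np.ndarray, window: tuple, bin_s: float) -> np.ndarray:
    c = binned_counts(spikes, events, window, bin_s)
    return c.sum(axis=0) / (len(events) * bin_s)


def ridge_significance(
    session: Session,
    unit_id: str,
    align_event: str = "sample_press",
    profile: str = "delay",
    delays=(10.0,),
    outcomes: Sequence[str] = ("correct",),
    background_window: tuple = BACKGROUND_WINDOW_S,
    rate_bin_s: float = RATE_BIN_S,
    ridge_bins: int = RIDGE_BINS,
    n_shifts: int = N_SHIFTS,
    rng: np.random.Generator | None = None,
    min_shift_s: float = MIN_SHIFT_S,
    null_shifts: np.ndarray | None = None,
) -> RidgeResult:
    """Ridge-to-background test of one unit against circular-shift surrogates."""
    if n_shifts < 100 and null_shifts is None:
        log.warning("n_shifts=%d is below the documented minimum of 100", n_shifts)
    rng = np.random.default_rng() if rng is None else rng
    df = session.trials.select(outcome=tuple(outcomes), delay_s=tuple(np.atleast_1d(delays)))
    events = event_times(session, align_event, df)
    events = events[np.isfinite(events)]
    if events.size == 0:
        raise ValueError("no qualifying trials for the ridge analysis")
    delay_ref = float(np.max(np.atleast_1d(delays)))
    peak_window = resolve_peak_window(profile, delay_ref)
    nb = int(round((background_window[1] - background_window[0]) / rate_bin_s))
    centers = background_window[0] + (np.arange(nb) + 0.5) * rate_bin_s
    spikes = session.unit(unit_id).spike_times_s
    duration = session.duration_s

    def stat(t: np.ndarray) -> float:
        r = _psth(t, events, background_window, rate_bin_s)
        return ridge_to_background(r, centers, peak_window, ridge_bins)[0]

    observed_psth = _psth(spikes, events, background_window, rate_bin_s)
    ratio, peak_time = ridge_to_background(observed_psth, centers, peak_window, ridge_bins)
    if null_shifts is None:
        null_shifts = rng.uniform(min_shift_s, duration - min_shift_s, n_shifts)
    null = np.array([stat(_rotate(spikes, s, duration)) for s in null_shifts])
    p = (1.0 + np.sum(null >= ratio)) / (1.0 + null.size)
    return RidgeResult(
        ratio=float(ratio),
        null_ratios=null,
        p=float(p),
        peak_time_s=peak_time,
        params={
            "rate_bin_s": rate_bin_s,
            "ridge_bins": ridge_bins,
            "background_window_s": tuple(background_window),
            "n_shifts": int(null.size),
            "align_event": align_event,
            "profile": profile,
        },
    )


def population_ridge_test(
    session: Session,
    unit_ids: Sequence[str] | None = None,
    rng: np.random.Generator | None = None,
    **kwargs,
) -> tuple[float, float, list[RidgeResult]]:
    """Population ridge statistic: mean ratio across units vs mean null ratios.

    Each unit gets its own independent shift offsets; the population null at
    shift index j is the across-unit mean of the units' j-th null ratios.
    Returns ``(mean_ratio, p, per_unit_results)``.
    """
    rng = np.random.default_rng() if rng is None else rng
    unit_ids = session.unit_ids if unit_ids is None else list(unit_ids)
    results = [ridge_significance(session, u, rng=rng, **kwargs) for u in unit_ids]
    mean_ratio = float(np.mean([r.ratio for r in results]))
    null_pop = np.mean([r.null_ratios for r in results], axis=0)
    p = (1.0 + np.sum(null_pop >= mean_ratio)) / (1.0 + null_pop.size)
    return mean_ratio, float(p), results


def peak_order_correlation(
    peaks_a: np.ndarray,
    peaks_b: np.ndarray,
    rng: np.random.Generator | None = None,
    exact_below_n: int = 30,
    n_resamples: int = 10_000,
) -> tuple[float, float]:
    """Spearman rank correlation between paired peak times (ties mid-ranked).

    For fewer than ``exact_below_n`` pairs the p-value comes from a seeded
    permutation test instead of the large-sample t approximation.
    """
    a, b = np.asarray(peaks_a, float), np.asarray(peaks_b, float)
    if a.size != b.size or a.size < 5:
        raise ValueError("need >= 5 paired peak times")
    r, p = stats.spearmanr(a, b)
    if a.size < exact_below_n:
        rng = np.random.default_rng(0) if rng is None else rng
        res = stats.permutation_test(
            (a, b),
            lambda x, y: stats.spearmanr(x, y).statistic,
            permutation_type="pairings",
            n_resamples=n_resamples,
            alternative="two-sided",
            rng=rng,
        )
        p = res.pvalue
    return float(r), float(p)


def peak_bias_test(peaks_observed: np.ndarray, peaks_null: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test between two peak-time samples."""
    res = stats.ranksums(np.asarray(peaks_observed, float), np.asarray(peaks_null, float))
    return float(res.statistic), float(res.pvalue)
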
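"""Event-aligned firing-rate estimation and derived maps.

Everything downstream (sequence statistics, information, decoding) consumes
peri-event rate estimates built here: spike counts binned relative to a task
event, averaged over trials, optionally Gaussian-smoothed (sigma = 1/6 s by
default), z-scored against a wide +/-50 s window, reduced to peak times, or
restricted to times the animal spent at the nose port.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .session_model import Session, TrackingTrace, detect_port_epochs, first_port_arrivals

__all__ = [
    "RateMap",
    "OccupancyMap",
    "event_times",
    "binned_counts",
    "estimate_rates",
    "smooth_rates",
    "zscore_rates",
    "peak_times",
    "sort_by_peak",
    "mask_by_port",
    "occupancy_map",
    "average_occupancy",
]

ALIGN_EVENTS = ("sample_press", "port_arrival", "nose_poke", "choice_press", "reward_entry")

DEFAULT_BIN_S = 0.05
DEFAULT_SIGMA_S = 1.0 / 6.0


@dataclass
class RateMap:
    """Units x bins event-aligned rate matrix with its metadata.

    ``mask`` (same shape, True = valid) marks bins excluded from analysis,
    e.g. because too few trials contributed port time there.
    """

    unit_ids: list
    align_event: str
    window: tuple
    bin_width_s: float
    rates: np.ndarray
    condition: str = "pooled"
    n_trials: dict | None = None
    mask: np.ndarray | None = None
    smoothed_sigma_s: float | None = None
    zscored: bool = False
    #: for port-masked maps: side -> per-bin total in-port exposure (seconds)
    exposure_s: dict | None = None

    @property
    def n_bins(self) -> int:
        return self.rates.shape[1]

    @property
    def bin_centers(self) -> np.ndarray:
        t0 = self.window[0]
        return t0 + (np.arange(self.n_bins) + 0.5) * self.bin_width_s

    def row(self, unit_id) -> np.ndarray:
        return self.rates[self.unit_ids.index(unit_id)]


@dataclass
class OccupancyMap:
    """Normalized head-position histogram on a 0.5 in grid (19 x 24 tiles)."""

    proportions: np.ndarray
    tile_size_in: float
    n_averaged: int = 1

    def __post_init__(self) -> None:
        if np.any(self.proportions < 0):
            raise ValueError("occupancy proportions must be non-negative")


def _n_bins(window: tuple, bin_width_s: float) -> int:
    return int(round((window[1] - window[0]) / bin_width_s))


def event_times(
    session: Session,
    align_event: str,
    trials_df=None,
    port_epochs: np.ndarray | None = None,
) -> np.ndarray:
    """Per-trial alignment times for ``align_event`` (NaN when absent).

    ``port_arrival`` is the first at-port epoch start after the sample press,
    derived from head tracking (port located from the nose-poke positions).
    """
    df = session.trials.df if trials_df is None else trials_df
    if align_event == "port_arrival":
        if port_epochs is None:
            pokes = session.trials.df["t_nose_poke"].dropna().to_numpy(float)
            port_epochs = detect_port_epochs(session.tracking, pokes)
        return first_port_arrivals(port_epochs, df["t_sample_press"].to_numpy(float))
    col = f"t_{align_event}"
    if col not in df.columns:
        raise ValueError(f"unknown align event {align_event!r}; choose one of {ALIGN_EVENTS}")
    return df[col].to_numpy(float)


def binned_counts(
    spike_times: np.ndarray, events: np.ndarray, window: tuple, bin_width_s: float
) -> np.ndarray:
    """Spike counts per (event, bin) for bins ``window[0]..window[1]`` around
    each event time.  Events that are NaN yield all-zero rows."""
    events = np.asarray(events, float)
    nb = _n_bins(window, bin_width_s)
    edges_rel = window[0] + np.arange(nb + 1) * bin_width_s
    out = np.zeros((events.size, nb), dtype=np.int64)
    finite = np.isfinite(events)
    if finite.any():
        abs_edges = events[finite, None] + edges_rel[None, :]
        idx = np.searchsorted(spike_times, abs_edges)
        out[finite] = np.diff(idx, axis=1)
    return out


def _select_trials(session: Session, delays, outcomes, condition):
    df = session.trials.df
    if outcomes is not None:
        df = df[df["outcome"].isin(tuple(outcomes))]
    if delays is not None:
        delays = (delays,) if np.isscalar(delays) else tuple(delays)
        df = df[df["delay_s"].isin(delays)]
    if condition in ("left", "right"):
        df = df[df["sample_side"] == condition]
    return df


def estimate_rates(
    session: Session,
    units: Sequence[str] | None = None,
    align_event: str = "sample_press",
    window: tuple = (-2.0, 12.0),
    bin_width_s: float = DEFAULT_BIN_S,
    condition: str = "pooled",
    delays=None,
    outcomes: Sequence[str] | None = ("correct",),
    port_epochs: np.ndarray | None = None,
) -> RateMap:
    """Trial-averaged peri-event rates (Hz) for the requested condition.

    ``condition='pooled'`` averages the left-trial and right-trial PSTHs
    (each side's histogram computed first, then the two averaged), so sides
    with unequal trial counts weigh equally.
    """
    unit_ids = list(units) if units is not None else session.unit_ids
    sides = ("left", "right") if condition == "pooled" else (condition,)
    per_side = {}
    n_trials = {}
    for side in sides:
        df = _select_trials(session, delays, outcomes, side)
        ev = event_times(session, align_event, df, port_epochs)
        ev = ev[np.isfinite(ev)]
        if ev.size == 0:
            raise ValueError(
                f"no qualifying trials for condition {side!r} "
                f"(delays={delays}, outcomes={outcomes}, align={align_event})"
            )
        n_trials[side] = ev.size
        rows = [
            binned_counts(session.unit(u).spike_times_s, ev, window, bin_width_s).sum(axis=0)
            / (ev.size * bin_width_s)
            for u in unit_ids
        ]
        per_side[side] = np.array(rows, dtype=float)
    rates = np.mean([per_side[s] for s in sides], axis=0)
    return RateMap(unit_ids, align_event, tuple(window), bin_width_s, rates, condition, n_trials)


def gaussian_kernel(sigma_s: float, bin_width_s: float) -> np.ndarray:
    """Unit-mass discrete Gaussian kernel truncated at +/-4 sigma."""
    half = max(1, int(np.ceil(4 * sigma_s / bin_width_s)))
    x = np.arange(-half, half + 1) * bin_width_s
    k = np.exp(-0.5 * (x / sigma_s) ** 2)
    return k / k.sum()


def smooth_rates(ratemap: RateMap, sigma_s: float = DEFAULT_SIGMA_S) -> RateMap:
    """Gaussian-smooth each row (kernel renormalized at edges and around
    masked bins, so constants are preserved)."""
    if ratemap.bin_width_s > sigma_s + 1e-12:
        raise ValueError("bin width must not exceed the smoothing sigma")
    k = gaussian_kernel(sigma_s, ratemap.bin_width_s)
    valid = (
        ratemap.mask.astype(float)
        if ratemap.mask is not None
        else np.ones_like(ratemap.rates)
    )
    num = np.array([np.convolve(r * v, k, mode="same") for r, v in zip(ratemap.rates, valid)])
    den = np.array([np.convolve(v, k, mode="same") for v in valid])
    with np.errstate(invalid="ignore", divide="ignore"):
        sm = np.where(den > 0, num / den, 0.0)
    return replace(ratemap, rates=sm, smoothed_sigma_s=sigma_s)


def zscore_rates(ratemap: RateMap, norm_window: tuple = (-50.0, 50.0)) -> RateMap:
    """Z-score each row against its mean/sd over ``norm_window``.

    The normalization window is truncated to the bins actually present;
    zero-variance rows map to all-zeros.
    """
    centers = ratemap.bin_centers
    in_win = (centers >= norm_window[0]) & (centers <= norm_window[1])
    if not in_win.any():
        raise ValueError("normalization window does not overlap the rate map")
    valid = np.broadcast_to(in_win, ratemap.rates.shape).copy()
    if ratemap.mask is not None:
        valid &= ratemap.mask
    out = np.zeros_like(ratemap.rates)
    for i, row in enumerate(ratemap.rates):
        sel = valid[i]
        if not sel.any():
            continue
        mu, sd = row[sel].mean(), row[sel].std()
        # relative tolerance: rounding in the smoothing of a constant row
        # must not masquerade as variance
        if sd > max(abs(mu), 1.0) * 1e-12:
            out[i] = (row - mu) / sd
    return replace(ratemap, rates=out, zscored=True)


def peak_times(ratemap: RateMap, search_window: tuple) -> np.ndarray:
    """Bin-center time of each row's maximum inside ``search_window``.

    Ties resolve to the earliest bin; rows fully masked inside the window
    yield NaN.
    """
    centers = ratemap.bin_centers
    sel = (centers >= search_window[0]) & (centers <= search_window[1])
    if not sel.any():
        raise ValueError("empty peak search window")
    vals = ratemap.rates[:, sel].astype(float).copy()
    if ratemap.mask is not None:
        vals[~ratemap.mask[:, sel]] = -np.inf
    out = centers[sel][np.argmax(vals, axis=1)]
    out = np.where(np.isfinite(vals).any(axis=1) & (np.max(vals, axis=1) > -np.inf), out, np.nan)
    return out


def sort_by_peak(ratemap: RateMap, reference_peaks: np.ndarray):
    """Order units by reference peak time (stable); returns (order, matrix)."""
    reference_peaks = np.asarray(reference_peaks, float)
    if reference_peaks.size != len(ratemap.unit_ids):
        raise ValueError("one reference peak per unit is required")
    order = np.argsort(reference_peaks, kind="stable")
    return order, ratemap.rates[order]


# ---------------------------------------------------------------------------
# Port-time masking
# ---------------------------------------------------------------------------

def _coverage_fn(epochs: np.ndarray):
    """Piecewise-linear cumulative in-port time: cum(t) = port time in [0,t)."""
    edges = np.asarray(epochs, float).ravel()
    durs = np.diff(epochs, axis=1).ravel()
    cum_at_edges = np.zeros(edges.size)
    cum_at_edges[1::2] = durs
    cum_at_edges = np.cumsum(cum_at_edges)
    # value at edges[2i] is total duration of epochs 0..i-1
    def cum(t):
        t = np.asarray(t, float)
        i = np.searchsorted(edges, t, side="right")
        base = np.where(i > 0, cum_at_edges[np.maximum(i - 1, 0)], 0.0)
        inside = (i % 2) == 1  # odd -> within an epoch
        extra = np.where(inside, t - edges[np.maximum(i - 1, 0)], 0.0)
        return base + extra
    return cum


def _spikes_in_port(spike_times: np.ndarray, epochs: np.ndarray) -> np.ndarray:
    i = np.searchsorted(epochs.ravel(), spike_times, side="right")
    return spike_times[(i % 2) == 1]


def mask_by_port(
    session: Session,
    units: Sequence[str] | None = None,
    align_event: str = "sample_press",
    window: tuple = (-2.0, 12.0),
    bin_width_s: float = 0.1,
    delays=None,
    outcomes: Sequence[str] | None = ("correct",),
    port_epochs: np.ndarray | None = None,
    min_trials_per_side: int = 25,
    condition: str = "pooled",
) -> RateMap:
    """Event-aligned rates using only time the rat spent at the nose port.

    Each bin's rate is (in-port spikes) / (in-port time) pooled over trials
    of a side — an occupancy-weighted estimate — then sides are averaged.
    Bins to which fewer than ``min_trials_per_side`` left trials and fewer
    than the same number of right trials contribute port time are masked.
    """
    if port_epochs is None:
        pokes = session.trials.df["t_nose_poke"].dropna().to_numpy(float)
        port_epochs = detect_port_epochs(session.tracking, pokes)
    cum = _coverage_fn(port_epochs)
    unit_ids = list(units) if units is not None else session.unit_ids
    nb = _n_bins(window, bin_width_s)
    edges_rel = window[0] + np.arange(nb + 1) * bin_width_s
    sides = ("left", "right") if condition == "pooled" else (condition,)
    side_rates, side_counts, side_exposure = {}, {}, {}
    for side in sides:
        df = _select_trials(session, delays, outcomes, side)
        ev = event_times(session, align_event, df, port_epochs)
        ev = ev[np.isfinite(ev)]
        if ev.size == 0:
            raise ValueError(f"no qualifying trials for condition {side!r}")
        abs_edges = ev[:, None] + edges_rel[None, :]
        port_time = np.diff(cum(abs_edges), axis=1)  # (trials, bins)
        spikes = {
            u: _spikes_in_port(session.unit(u).spike_times_s, port_epochs) for u in unit_ids
        }
        tot_time = port_time.sum(axis=0)
        rates = np.zeros((len(unit_ids), nb))
        for r, u in enumerate(unit_ids):
            cnt = binned_counts(spikes[u], ev, window, bin_width_s).sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                rates[r] = np.where(tot_time > 0, cnt / np.maximum(tot_time, 1e-12), 0.0)
        side_rates[side] = rates
        side_counts[side] = (port_time > 1e-9).sum(axis=0)  # contributing trials per bin
        side_exposure[side] = tot_time
    rates = np.mean([side_rates[s] for s in sides], axis=0)
    if condition == "pooled":
        thin = (side_counts["left"] < min_trials_per_side) & (
            side_counts["right"] < min_trials_per_side
        )
    else:
        thin = side_counts[condition] < min_trials_per_side
    mask = np.broadcast_to(~thin, rates.shape).copy()
    return RateMap(
        unit_ids, align_event, tuple(window), bin_width_s, rates, condition,
        {s: int(side_counts[s].max(initial=0)) for s in sides}, mask=mask,
        exposure_s=side_exposure,
    )


# ---------------------------------------------------------------------------
# Occupancy maps
# ---------------------------------------------------------------------------

def occupancy_map(
    tracking: TrackingTrace,
    windows: Sequence[tuple],
    tile_size_in: float = 0.5,
    chamber: tuple = (9.5, 12.0),
) -> OccupancyMap:
    """Normalized histogram of head positions over the given time windows.

    Tiles are half-open on the low edge (points on an interior edge go to the
    lower-index tile); the map sums to 1.
    """
    w, h = chamber
    sel = np.zeros(tracking.t_s.size, dtype=bool)
    for t0, t1 in windows:
        sel |= (tracking.t_s >= t0) & (tracking.t_s < t1)
    if not sel.any():
        raise ValueError("no tracking frames inside the requested windows")
    nx, ny = int(round(w / tile_size_in)), int(round(h / tile_size_in))
    ix = np.clip((tracking.x_in[sel] / tile_size_in).astype(int), 0, nx - 1)
    iy = np.clip((tracking.y_in[sel] / tile_size_in).astype(int), 0, ny - 1)
    counts = np.zeros((nx, ny))
    np.add.at(counts, (ix, iy), 1.0)
    return OccupancyMap(counts / counts.sum(), tile_size_in)


def average_occupancy(maps: Sequence[OccupancyMap]) -> OccupancyMap:
    """Average per-session-normalized maps (mean of proportions)."""
    if not maps:
        raise ValueError("no maps to average")
    tiles = {m.tile_size_in for m in maps}
    if len(tiles) != 1:
        raise ValueError("maps use different tile sizes")
    return OccupancyMap(
        np.mean([m.proportions for m in maps], axis=0), maps[0].tile_size_in, len(maps)
    )
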
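"""Maximum-likelihood Poisson population decoding of the sample stimulus.

The decoder assumes each unit's spiking is an inhomogeneous Poisson process
with side-conditional rate functions (smoothed condition PSTHs trained on
correct trials).  Given an N x k matrix S of spike counts (N units, k bins
of 50 ms inside a 500 ms window) it picks the side x maximizing::

    sum_i sum_j log Poisson(S_ij ; lambda_x,i(bin_j) * 0.05 s)

which under a uniform prior is the maximum a-posteriori sample side.  Since
units are generally not recorded simultaneously, evaluation uses
*pseudo-trials*: for each pseudo-trial every unit contributes the counts of
one real trial drawn (with replacement) from a fixed condition.  The
correct-trial accuracy trace uses leave-one-out cross-validation — each
unit's held-out source trial is removed from that unit's training PSTH.
Error-trial evaluation scores a correct-trial-trained decoder against the
sample label, so below-chance accuracy reveals choice (action) coding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .rate_maps import DEFAULT_BIN_S, DEFAULT_SIGMA_S, binned_counts, gaussian_kernel
from .sample_info import RATE_FLOOR_HZ
from .session_model import Session, detect_port_epochs, first_port_arrivals

__all__ = [
    "PseudoTrialSet",
    "DecodeTrace",
    "PoissonPopulationDecoder",
    "decode_window",
    "build_pseudo_trials",
    "loo_accuracy_trace",
    "error_trial_trace",
    "port_aligned_decode",
]

N_PSEUDO = 500
WINDOW_S = 0.5

SIDES = ("left", "right")


@dataclass
class PseudoTrialSet:
    """Pseudo-trial assignments for one (side, outcome) condition.

    ``assignments[i, j]`` is the index (into ``source_trials``) of the real
    trial contributed by unit j on pseudo-trial i; every unit contributes
    exactly one source trial per pseudo-trial, drawn with replacement.
    """

    condition: tuple
    source_trials: np.ndarray  # trial_index values available in the condition
    assignments: np.ndarray  # (n_pseudo, n_units) indices into source_trials
    unit_ids: list
    seed: int | None = None

    @property
    def n_pseudo(self) -> int:
        return self.assignments.shape[0]


@dataclass
class DecodeTrace:
    """Time course of decoding accuracy with its SEM upper bound."""

    window_centers_s: np.ndarray
    accuracy: np.ndarray
    sem_upper: np.ndarray
    eval_set: str
    n_min: int
    params: dict = field(default_factory=dict)


def decode_window(
    S: np.ndarray,
    lam_left: np.ndarray,
    lam_right: np.ndarray,
    dt: float = DEFAULT_BIN_S,
    rng: np.random.Generator | None = None,
    floor_hz: float = RATE_FLOOR_HZ,
) -> str:
    """Decode one N x k count matrix against N x k side-conditional rates.

    Exact likelihood ties are broken by a fair coin from ``rng``.
    """
    S = np.asarray(S)
    if S.shape != np.shape(lam_left) or S.shape != np.shape(lam_right):
        raise ValueError("count matrix and rate models have mismatched shapes")
    if np.any(S < 0) or not np.issubdtype(S.dtype, np.integer) and np.any(S != np.round(S)):
        raise ValueError("counts must be non-negative integers")
    ll = []
    for lam in (lam_left, lam_right):
        mu = np.maximum(lam, floor_hz) * dt
        ll.append(float((S * np.log(mu)).sum() - mu.sum()))
    if ll[0] == ll[1]:
        rng = np.random.default_rng() if rng is None else rng
        return SIDES[int(rng.integers(0, 2))]
    return "left" if ll[0] > ll[1] else "right"


def build_pseudo_trials(
    session: Session,
    units: Sequence[str] | None = None,
    condition: tuple = ("left", "correct"),
    n: int = N_PSEUDO,
    rng: np.random.Generator | None = None,
    delays=(10.0,),
) -> PseudoTrialSet:
    """Draw pseudo-trial assignments for one (side, outcome) condition."""
    rng = np.random.default_rng() if rng is None else rng
    unit_ids = session.unit_ids if units is None else list(units)
    side, outcome = condition
    df = session.trials.select(outcome=outcome, delay_s=tuple(np.atleast_1d(delays)),
                               sample_side=side)
    df = df[np.isfinite(df["t_sample_press"].to_numpy(float))]
    if len(df) == 0:
        raise ValueError(f"no trials in condition {condition} (delays={delays})")
    source = df["trial_index"].to_numpy(int)
    assignments = rng.integers(0, source.size, size=(n, len(unit_ids)))
    return PseudoTrialSet(tuple(condition), source, assignments, unit_ids)


class PoissonPopulationDecoder:
    """Maximum-likelihood Poisson decoder over a pseudo-population.

    Parameters mirror the analysis conventions: 50 ms bins, sigma = 1/6 s
    smoothing, 500 ms decoding windows, and a 0.01 Hz rate floor.  ``fit``
    estimates per-unit side-conditional rate models from the supplied
    (correct) trials; fitted attributes carry a trailing underscore.
    """

    def __init__(
        self,
        bin_s: float = DEFAULT_BIN_S,
        sigma_s: float = DEFAULT_SIGMA_S,
        model_window: tuple = (-1.0, 11.0),
        floor_hz: float = RATE_FLOOR_HZ,
    ):
        self.bin_s = bin_s
        self.sigma_s = sigma_s
        self.model_window = tuple(model_window)
        self.floor_hz = floor_hz

    # -- fitting -----------------------------------------------------------
    def fit(
        self,
        session: Session,
        units: Sequence[str] | None = None,
        events_by_side: dict | None = None,
        delays=(10.0,),
        align_event: str = "sample_press",
    ) -> "PoissonPopulationDecoder":
        """Fit side-conditional rate models from correct trials.

        ``events_by_side`` may supply explicit alignment times per side
        (e.g. port arrivals); otherwise correct trials of ``delays`` aligned
        to ``align_event`` are used.
        """
        self.unit_ids_ = session.unit_ids if units is None else list(units)
        if events_by_side is None:
            events_by_side = {}
            for side in SIDES:
                df = session.trials.select(
                    outcome="correct", delay_s=tuple(np.atleast_1d(delays)), sample_side=side
                )
                col = f"t_{align_event}"
                ev = df[col].to_numpy(float)
                events_by_side[side] = ev[np.isfinite(ev)]
        for side in SIDES:
            if len(events_by_side[side]) < 2:
                raise ValueError(f"need >= 2 training trials on side {side!r}")
        self.events_ = {s: np.asarray(events_by_side[s], float) for s in SIDES}
        kernel = gaussian_kernel(self.sigma_s, self.bin_s)
        nb = int(round((self.model_window[1] - self.model_window[0]) / self.bin_s))
        ones = np.convolve(np.ones(nb), kernel, mode="same")
        self.counts_, self.counts_sm_, self.lam_ = {}, {}, {}
        for side in SIDES:
            ev = self.events_[side]
            C = np.array(
                [
                    binned_counts(session.unit(u).spike_times_s, ev, self.model_window, self.bin_s)
                    for u in self.unit_ids_
                ]
            )  # (N, n_trials, nb)
            Csm = np.apply_along_axis(
                lambda r: np.convolve(r, kernel, mode="same") / ones, 2, C.astype(float)
            )
            self.counts_[side] = C
            self.counts_sm_[side] = Csm
            self.lam_[side] = Csm.mean(axis=1) / self.bin_s  # (N, nb) smoothed Hz
        self.n_min_ = min(self.events_[s].size for s in SIDES)
        self.bin_centers_ = (
            self.model_window[0] + (np.arange(nb) + 0.5) * self.bin_s
        )
        return self

    def _window_slice(self, t_center: float, window_s: float = WINDOW_S) -> slice:
        sel = np.flatnonzero(
            (self.bin_centers_ > t_center - window_s / 2)
            & (self.bin_centers_ < t_center + window_s / 2)
        )
        if sel.size == 0:
            raise ValueError(f"decode window at {t_center} s outside the model window")
        return slice(sel[0], sel[-1] + 1)

    def decode(self, S: np.ndarray, t_center: float, rng=None, window_s: float = WINDOW_S) -> str:
        """Decode one pseudo-trial count matrix at ``t_center``."""
        sl = self._window_slice(t_center, window_s)
        return decode_window(
            S, self.lam_["left"][:, sl], self.lam_["right"][:, sl], self.bin_s, rng, self.floor_hz
        )

    # -- batched pseudo-trial evaluation ----------------------------------
    def _loglik_diff(
        self,
        counts_eval: dict,
        assignments: np.ndarray,
        sl: slice,
        loo_side: str | None = None,
    ) -> np.ndarray:
        """log L(left) - log L(right) for each pseudo-trial.

        ``counts_eval[u]`` are the (n_trials, nb) raw counts of the evaluated
        condition; when ``loo_side`` is given, that side's training PSTH
        excludes the held-out source trial of each pseudo-trial (valid when
        the evaluated trials are the training trials of ``loo_side``).
        """
        n_pseudo, n_units = assignments.shape
        diff = np.zeros(n_pseudo)
        dt = self.bin_s
        for j in range(n_units):
            a = assignments[:, j]
            s = counts_eval[j][a][:, sl]  # (n_pseudo, k)
            lam = {}
            for side in SIDES:
                if side == loo_side:
                    n_tr = self.counts_[side].shape[1]
                    base = self.counts_sm_[side][j].sum(axis=0)  # (nb,)
                    lam_side = (base[None, :] - self.counts_sm_[side][j][a]) / (
                        (n_tr - 1) * dt
                    )
                else:
                    lam_side = self.lam_[side][j][None, :]
                lam[side] = np.maximum(lam_side[:, sl], self.floor_hz) * dt
            diff += (s * (np.log(lam["left"]) - np.log(lam["right"]))).sum(axis=1)
            diff += (lam["right"] - lam["left"]).sum(axis=1)
        return diff

    def accuracy_trace(
        self,
        session: Session,
        centers: np.ndarray,
        eval_events: dict,
        true_sides: str = "sample",
        n_pseudo: int = N_PSEUDO,
        rng: np.random.Generator | None = None,
        loo: bool = False,
        window_s: float = WINDOW_S,
        eval_set: str = "loo_correct",
    ) -> DecodeTrace:
        """Accuracy of pseudo-trial decoding at each window center.

        ``eval_events`` maps the *sample* side to that condition's alignment
        times.  With ``loo=True`` the evaluated events must be the training
        events and leave-one-out exclusion is applied.
        """
        rng = np.random.default_rng() if rng is None else rng
        counts_eval, assignments = {}, {}
        for side in SIDES:
            ev = np.asarray(eval_events[side], float)
            if ev.size == 0:
                raise ValueError(f"no evaluation trials with sample side {side!r}")
            if loo:
                counts_eval[side] = {
                    j: self.counts_[side][j] for j in range(len(self.unit_ids_))
                }
            else:
                counts_eval[side] = {
                    j: binned_counts(
                        session.unit(u).spike_times_s, ev, self.model_window, self.bin_s
                    )
                    for j, u in enumerate(self.unit_ids_)
                }
            assignments[side] = rng.integers(0, ev.size, size=(n_pseudo, len(self.unit_ids_)))
        centers = np.asarray(centers, float)
        acc = np.empty(centers.size)
        for i, c in enumerate(centers):
            sl = self._window_slice(c, window_s)
            correct = 0
            total = 0
            for side in SIDES:
                d = self._loglik_diff(
                    counts_eval[side],
                    assignments[side],
                    sl,
                    loo_side=side if loo else None,
                )
                coin = rng.random(d.size) < 0.5
                decoded_left = np.where(d == 0, coin, d > 0)
                correct += int(np.sum(decoded_left == (side == "left")))
                total += d.size
            acc[i] = correct / total
        n_min_eval = min(
            min(np.asarray(eval_events[s]).size for s in SIDES), self.n_min_
        )
        sem = np.sqrt(acc * (1 - acc) / n_min_eval)
        return DecodeTrace(
            centers,
            acc,
            sem,
            eval_set,
            int(n_min_eval),
            params={
                "window_s": window_s,
                "bin_s": self.bin_s,
                "k": int(round(window_s / self.bin_s)),
                "N": len(self.unit_ids_),
                "n_pseudo": n_pseudo,
            },
        )


def _default_centers(delay: float, stride_s: float, window_s: float = WINDOW_S) -> np.ndarray:
    n = int(np.floor((delay - window_s) / stride_s + 1e-9)) + 1
    return window_s / 2 + stride_s * np.arange(n)


def loo_accuracy_trace(
    session: Session,
    units: Sequence[str] | None = None,
    delays=(10.0,),
    stride_s: float = 0.25,
    n_pseudo: int = N_PSEUDO,
    rng: np.random.Generator | None = None,
    centers: np.ndarray | None = None,
    decoder: PoissonPopulationDecoder | None = None,
) -> DecodeTrace:
    """Leave-one-out correct-trial decoding accuracy across the delay."""
    rng = np.random.default_rng() if rng is None else rng
    delay = float(np.max(np.atleast_1d(delays)))
    if decoder is None:
        decoder = PoissonPopulationDecoder(model_window=(-1.0, delay + 1.0))
    decoder.fit(session, units, delays=delays)
    if centers is None:
        centers = _default_centers(delay, stride_s)
    return decoder.accuracy_trace(
        session, centers, decoder.events_, n_pseudo=n_pseudo, rng=rng, loo=True,
        eval_set="loo_correct",
    )


def error_trial_trace(
    session: Session,
    units: Sequence[str] | None = None,
    delays=(10.0,),
    align_event: str = "sample_press",
    stride_s: float = 0.25,
    n_pseudo: int = N_PSEUDO,
    rng: np.random.Generator | None = None,
    centers: np.ndarray | None = None,
    model_window: tuple | None = None,
) -> DecodeTrace:
    """Error-trial generalization of a correct-trial-trained decoder.

    Accuracy is scored against the *sample* label; sustained below-chance
    accuracy means the population reflects the upcoming (matching) choice
    rather than the remembered sample.
    """
    rng = np.random.default_rng() if rng is None else rng
    delay = float(np.max(np.atleast_1d(delays)))
    if model_window is None:
        model_window = (-1.0, delay + 1.0) if align_event == "sample_press" else (-2.0, 2.0)
    decoder = PoissonPopulationDecoder(model_window=model_window)
    train_events = {}
    eval_events = {}
    col = f"t_{align_event}"
    for side in SIDES:
        tr = session.trials.select(outcome="correct", delay_s=tuple(np.atleast_1d(delays)),
                                   sample_side=side)
        ev = tr[col].to_numpy(float)
        train_events[side] = ev[np.isfinite(ev)]
        er = session.trials.select(outcome="error", delay_s=tuple(np.atleast_1d(delays)),
                                   sample_side=side)
        ee = er[col].to_numpy(float)
        eval_events[side] = ee[np.isfinite(ee)]
        if eval_events[side].size == 0:
            raise ValueError(f"no error trials with sample side {side!r}")
    decoder.fit(session, units, events_by_side=train_events)
    if centers is None:
        if align_event == "sample_press":
            centers = _default_centers(delay, stride_s)
        else:
            centers = np.arange(model_window[0] + 0.3, model_window[1] - 0.3 + 1e-9, stride_s)
    trace = decoder.accuracy_trace(
        session, centers, eval_events, n_pseudo=n_pseudo, rng=rng, loo=False,
        eval_set="error_trials",
    )
    n_min_eval = min(
        min(eval_events[s].size for s in SIDES), min(train_events[s].size for s in SIDES)
    )
    trace.n_min = int(n_min_eval)
    trace.sem_upper = np.sqrt(trace.accuracy * (1 - trace.accuracy) / n_min_eval)
    return trace


def port_aligned_decode(
    session: Session,
    units: Sequence[str] | None = None,
    delays=(10.0,),
    min_dwell_s: float = 1.5,
    stride_s: float = 0.25,
    n_pseudo: int = N_PSEUDO,
    rng: np.random.Generator | None = None,
    centers: np.ndarray | None = None,
    model_window: tuple = (-1.0, 3.0),
) -> DecodeTrace:
    """LOO decoding aligned to the first nose-port arrival of each trial.

    Trials in which the rat left the port within ``min_dwell_s`` of arrival
    are excluded, and the default evaluation windows lie inside the first
    ``min_dwell_s`` after arrival, when every included trial is still at the
    port.  Aligning at the port equalizes head position across sample sides,
    so selectivity that was really positional disappears.
    """
    rng = np.random.default_rng() if rng is None else rng
    pokes = session.trials.df["t_nose_poke"].dropna().to_numpy(float)
    epochs = detect_port_epochs(session.tracking, pokes)
    events_by_side = {}
    for side in SIDES:
        df = session.trials.select(outcome="correct", delay_s=tuple(np.atleast_1d(delays)),
                                   sample_side=side)
        arrivals = first_port_arrivals(epochs, df["t_sample_press"].to_numpy(float))
        keep = np.isfinite(arrivals)
        arr = arrivals[keep]
        # dwell of the epoch the arrival starts
        starts = epochs[:, 0]
        idx = np.searchsorted(starts, arr, side="right") - 1
        dwell = epochs[idx, 1] - arr
        arr = arr[dwell >= min_dwell_s]
        if arr.size < 2:
            raise ValueError(
                f"fewer than 2 qualifying port-aligned trials on side {side!r} "
                f"after the {min_dwell_s} s dwell exclusion"
            )
        events_by_side[side] = arr
    decoder = PoissonPopulationDecoder(model_window=model_window)
    decoder.fit(session, units, events_by_side=events_by_side)
    if centers is None:
        centers = np.arange(WINDOW_S / 2, min_dwell_s - WINDOW_S / 2 + 1e-9, stride_s)
    return decoder.accuracy_trace(
        session, centers, events_by_side, n_pseudo=n_pseudo, rng=rng, loo=True,
        eval_set="port_aligned",
    )
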
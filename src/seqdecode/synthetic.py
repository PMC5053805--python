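"""Generative model of DNMP sessions: behavior, head tracking, and spiking.

The simulator reproduces the structure of an operant delayed
non-match-to-position session so that every analysis stage has a ground
truth to recover:

* a trial state machine with the task's timing rules (30 s to press the
  sample lever, a 1/5/10 s delay, 5 s to poke the lit nose port, 5 s to press
  a choice lever, 5 s timeout on errors, 10 s inter-trial interval);
* a waypoint trajectory (lever wall -> nose port -> lever wall -> reward
  receptacle) with a dwell at the port covering the delay, constant-speed
  segments and Gaussian position jitter;
* inhomogeneous-Poisson spiking by thinning against a per-unit rate function
  built from a baseline, a delay-aligned Gaussian "sequence" bump, a
  multiplicative sample-side selectivity gain inside a time envelope, an
  optional 2-D Gaussian position field, and an optional choice-press bump.

Behavioral accuracy is imposed (outcomes are sampled from per-delay accuracy
targets), not emergent: the artifact tests analyses, not cognition.  One RNG
stream drives behavior and one more drives each unit, all spawned from the
session seed, so adding units never perturbs behavior.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .session_model import (
    CHAMBER_HEIGHT_IN,
    CHAMBER_WIDTH_IN,
    EVENT_COLUMNS,
    Session,
    SpikeTrain,
    TrackingTrace,
    TrialTable,
)

__all__ = [
    "PositionField",
    "NeuronTuning",
    "SynthConfig",
    "GroundTruth",
    "simulate_behavior",
    "simulate_spikes",
    "simulate_session",
    "make_preset_session",
    "PRESETS",
]

# Chamber landmarks (inches; origin = left corner of the nose-port wall).
PORT_XY = (CHAMBER_WIDTH_IN / 2, 0.5)
LEFT_LEVER_XY = (2.0, CHAMBER_HEIGHT_IN - 0.5)
RIGHT_LEVER_XY = (CHAMBER_WIDTH_IN - 2.0, CHAMBER_HEIGHT_IN - 0.5)
REWARD_XY = (CHAMBER_WIDTH_IN / 2, CHAMBER_HEIGHT_IN - 0.5)
CENTER_XY = (CHAMBER_WIDTH_IN / 2, CHAMBER_HEIGHT_IN / 2)

_OPPOSITE = {"left": "right", "right": "left"}


@dataclass
class PositionField:
    """2-D Gaussian place-like field over the chamber."""

    x_in: float
    y_in: float
    sigma_in: float
    gain_hz: float


@dataclass
class NeuronTuning:
    """Parameters of one simulated unit's rate function.

    The rate at time t is::

        r(t) = [baseline + seq bump(t)] * sample gain(t) * choice gain(t)
               + position field(x(t), y(t))

    where the sequence bump is a Gaussian of amplitude ``seq_gain_hz`` at
    ``seq_peak_time_s`` after delay onset on every trial with a sample press,
    the sample gain equals ``selectivity_gain`` inside ``selectivity_envelope``
    (relative to delay onset) on trials of ``preferred_side`` and 1 elsewhere,
    and the choice gain acts analogously around the choice press.
    """

    baseline_hz: float = 1.0
    seq_peak_time_s: float | None = None
    seq_width_s: float = 0.5
    seq_gain_hz: float = 0.0
    selectivity_gain: float = 1.0
    selectivity_envelope: tuple[float, float] | None = None
    preferred_side: str = "none"
    position_field: PositionField | None = None
    choice_selectivity_gain: float = 1.0
    choice_envelope: tuple[float, float] | None = None
    choice_preferred_side: str = "none"

    def validate(self) -> None:
        if self.baseline_hz < 0 or self.seq_gain_hz < 0:
            raise ValueError("rates must be non-negative")
        if self.selectivity_gain < 0 or self.choice_selectivity_gain < 0:
            raise ValueError("gains must be non-negative")
        for env in (self.selectivity_envelope, self.choice_envelope):
            if env is not None and env[1] <= env[0]:
                raise ValueError(f"envelope {env} is not a valid interval")


@dataclass
class SynthConfig:
    """Full parameterization of the generative session model.

    Latencies are log-normal; the defaults give medians of 2.5 s (sample
    press), 0.4 s (nose poke after port light) and 1.2 s (choice press),
    matching an engaged, well-trained animal.
    """

    n_trials: int = 300
    delay_set: tuple[float, ...] = (1.0, 5.0, 10.0)
    p_correct: dict = field(default_factory=lambda: {1.0: 0.9, 5.0: 0.8, 10.0: 0.7})
    omission_rate: float = 0.03
    abort_rate: float = 0.02
    sample_press_median_s: float = 2.5
    sample_press_sigma: float = 0.6
    poke_median_s: float = 0.4
    poke_sigma: float = 0.5
    choice_median_s: float = 1.2
    choice_sigma: float = 0.5
    iti_s: float = 10.0
    timeout_s: float = 5.0
    sample_window_s: float = 30.0
    response_window_s: float = 5.0
    tracking_rate_hz: float = 30.0
    travel_speed_in_s: float = 8.0
    jitter_in: float = 0.12
    tunings: list[NeuronTuning] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        for p in (self.omission_rate, self.abort_rate, *self.p_correct.values()):
            if not 0 <= p <= 1:
                raise ValueError(f"probability {p} outside [0, 1]")
        if not self.delay_set:
            raise ValueError("delay set is empty")
        for m in (self.sample_press_median_s, self.poke_median_s, self.choice_median_s):
            if m <= 0:
                raise ValueError("latency medians must be positive")
        for t in self.tunings:
            t.validate()


@dataclass
class GroundTruth:
    """Planted structure of a simulated session, for oracle-based tests."""

    tunings: list[NeuronTuning]
    choice_side: list  # actual choice per trial (None when no choice press)
    dwell_log: np.ndarray  # (n_dwells, 2) port [arrival, leave) times
    dwell_trial: np.ndarray  # trial index of each dwell
    rate_samples: dict = field(default_factory=dict)  # unit_id -> rate on grid


# ---------------------------------------------------------------------------
# Behavior + tracking
# ---------------------------------------------------------------------------

def _lognormal(rng: np.random.Generator, median: float, sigma: float, cap: float) -> float:
    return min(float(rng.lognormal(np.log(median), sigma)), cap)


def simulate_behavior(
    config: SynthConfig, rng: np.random.Generator
) -> tuple[TrialTable, TrackingTrace, GroundTruth]:
    """Run the trial state machine and synthesize the head trajectory."""
    config.validate()
    rows = []
    waypoints: list[tuple[float, float, float]] = []  # (t, x, y) breakpoints
    dwells: list[tuple[float, float]] = []
    dwell_trial: list[int] = []
    choice_sides: list = []
    speed = config.travel_speed_in_s

    def travel_time(a, b) -> float:
        return float(np.hypot(a[0] - b[0], a[1] - b[1]) / speed)

    t = 2.0  # short warm-up before the first trial
    waypoints.append((0.0, *CENTER_XY))
    for k in range(config.n_trials):
        side = "left" if rng.random() < 0.5 else "right"
        delay = float(rng.choice(config.delay_set))
        lever = LEFT_LEVER_XY if side == "left" else RIGHT_LEVER_XY
        ev = dict.fromkeys(EVENT_COLUMNS, np.nan)
        ev["t_sample_present"] = t

        if rng.random() < config.omission_rate:
            # never presses the sample lever: wanders near the lever wall
            waypoints.append((t + 3.0, *CENTER_XY))
            waypoints.append((t + config.sample_window_s, *CENTER_XY))
            outcome = "sample_omission"
            choice_sides.append(None)
            t += config.sample_window_s + config.timeout_s + config.iti_s
            rows.append(
                dict(trial_index=k, sample_side=side, delay_s=delay, outcome=outcome, **ev)
            )
            continue

        press = t + max(0.3, _lognormal(rng, config.sample_press_median_s,
                                        config.sample_press_sigma, config.sample_window_s - 0.1))
        ev["t_sample_press"] = press
        port_on = press + delay
        ev["t_port_on"] = port_on
        waypoints.append((press, *lever))

        if rng.random() < config.abort_rate:
            # never pokes the lit port: drifts around the chamber instead
            waypoints.append((press + 2.0, *CENTER_XY))
            waypoints.append((port_on + config.response_window_s, *CENTER_XY))
            outcome = "abort"
            choice_sides.append(None)
            t = port_on + config.response_window_s + config.timeout_s + config.iti_s
            rows.append(
                dict(trial_index=k, sample_side=side, delay_s=delay, outcome=outcome, **ev)
            )
            continue

        poke = port_on + max(0.05, _lognormal(rng, config.poke_median_s, config.poke_sigma,
                                              config.response_window_s - 0.1))
        ev["t_nose_poke"] = poke
        # rat runs to the port right after the press and waits out the delay
        arrive = min(press + travel_time(lever, PORT_XY), poke - 0.1)
        leave = poke + 0.2
        waypoints.append((arrive, *PORT_XY))
        waypoints.append((leave, *PORT_XY))
        dwells.append((arrive, leave))
        dwell_trial.append(k)

        correct = rng.random() < config.p_correct.get(delay, 0.5)
        choice_side = _OPPOSITE[side] if correct else side
        choice_sides.append(choice_side)
        choice_lever = LEFT_LEVER_XY if choice_side == "left" else RIGHT_LEVER_XY
        choice = poke + max(
            travel_time(PORT_XY, choice_lever) + 0.05,
            _lognormal(rng, config.choice_median_s, config.choice_sigma,
                       config.response_window_s - 0.1),
        )
        ev["t_choice_press"] = choice
        waypoints.append((choice, *choice_lever))

        if correct:
            outcome = "correct"
            reward = choice + 0.8 + 0.4 * rng.random()
            ev["t_reward_entry"] = reward
            waypoints.append((reward, *REWARD_XY))
            waypoints.append((reward + 2.5, *REWARD_XY))  # consume
            t = reward + 2.5 + config.iti_s
        else:
            outcome = "error"
            waypoints.append((choice + 2.0, *CENTER_XY))
            t = choice + config.timeout_s + config.iti_s
        rows.append(dict(trial_index=k, sample_side=side, delay_s=delay, outcome=outcome, **ev))

    duration = t + 5.0
    waypoints.append((duration, *CENTER_XY))
    tracking = _render_trajectory(waypoints, duration, config, rng)
    trials = TrialTable(pd.DataFrame(rows))
    truth = GroundTruth(
        tunings=list(config.tunings),
        choice_side=choice_sides,
        dwell_log=np.array(dwells).reshape(-1, 2),
        dwell_trial=np.array(dwell_trial, dtype=int),
    )
    return trials, tracking, truth


def _render_trajectory(
    waypoints: list[tuple[float, float, float]],
    duration: float,
    config: SynthConfig,
    rng: np.random.Generator,
) -> TrackingTrace:
    wp = np.array(waypoints)
    order = np.argsort(wp[:, 0], kind="stable")
    wp = wp[order]
    dt = 1.0 / config.tracking_rate_hz
    t = np.arange(0.0, duration, dt)
    x = np.interp(t, wp[:, 0], wp[:, 1]) + rng.normal(0, config.jitter_in, t.size)
    y = np.interp(t, wp[:, 0], wp[:, 2]) + rng.normal(0, config.jitter_in, t.size)
    np.clip(x, 0.0, CHAMBER_WIDTH_IN, out=x)
    np.clip(y, 0.0, CHAMBER_HEIGHT_IN, out=y)
    vx = np.gradient(x, t)
    vy = np.gradient(y, t)
    sp = np.hypot(vx, vy)
    heading = np.degrees(np.arctan2(vy, vx)) % 360.0
    # hold the last moving heading while (nearly) stationary
    moving = sp > 1.0
    if not moving[0]:
        heading[0] = 180.0  # facing the port wall at session start
        moving[0] = True
    idx = np.maximum.accumulate(np.where(moving, np.arange(t.size), 0))
    heading = heading[idx]
    return TrackingTrace(t, x, y, heading, vx, vy, sp)


# ---------------------------------------------------------------------------
# Spiking
# ---------------------------------------------------------------------------

def rate_on_grid(
    tuning: NeuronTuning,
    trials: TrialTable,
    tracking: TrackingTrace,
    choice_side: Sequence | None = None,
) -> np.ndarray:
    """Evaluate the unit's true rate function on the tracking time grid (Hz)."""
    t = tracking.t_s
    rate = np.full(t.size, float(tuning.baseline_hz))
    df = trials.df
    presses = df["t_sample_press"].to_numpy(float)
    sides = df["sample_side"].to_numpy()
    if tuning.seq_gain_hz > 0 and tuning.seq_peak_time_s is not None:
        w = tuning.seq_width_s
        for d0 in presses[np.isfinite(presses)]:
            c = d0 + tuning.seq_peak_time_s
            lo, hi = np.searchsorted(t, [c - 5 * w, c + 5 * w])
            rate[lo:hi] += tuning.seq_gain_hz * np.exp(-0.5 * ((t[lo:hi] - c) / w) ** 2)
    if tuning.selectivity_envelope is not None and tuning.preferred_side in ("left", "right"):
        e0, e1 = tuning.selectivity_envelope
        for d0, side in zip(presses, sides):
            if np.isfinite(d0) and side == tuning.preferred_side:
                lo, hi = np.searchsorted(t, [d0 + e0, d0 + e1])
                rate[lo:hi] *= tuning.selectivity_gain
    if tuning.choice_envelope is not None and tuning.choice_preferred_side in ("left", "right"):
        if choice_side is None:
            raise ValueError("choice-tuned unit needs the per-trial choice sides")
        e0, e1 = tuning.choice_envelope
        chpress = df["t_choice_press"].to_numpy(float)
        for tc, ch in zip(chpress, choice_side):
            if np.isfinite(tc) and ch == tuning.choice_preferred_side:
                lo, hi = np.searchsorted(t, [tc + e0, tc + e1])
                rate[lo:hi] *= tuning.choice_selectivity_gain
    if tuning.position_field is not None:
        f = tuning.position_field
        d2 = (tracking.x_in - f.x_in) ** 2 + (tracking.y_in - f.y_in) ** 2
        rate += f.gain_hz * np.exp(-0.5 * d2 / f.sigma_in**2)
    np.clip(rate, 0.0, None, out=rate)
    return rate


def _thin_poisson(
    rate: np.ndarray, t_grid: np.ndarray, rng: np.random.Generator, block: int = 256
) -> np.ndarray:
    """Inhomogeneous-Poisson times by thinning with piecewise ceilings.

    The ceiling is the running maximum of the rate over blocks of ``block``
    frames (widened to neighboring blocks so linear interpolation between
    grid points never exceeds it).
    """
    dt = t_grid[1] - t_grid[0]
    n = rate.size
    nb = int(np.ceil(n / block))
    padded = np.full(nb * block, 0.0)
    padded[:n] = rate
    block_max = padded.reshape(nb, block).max(axis=1)
    ceil = np.maximum(block_max, np.maximum(np.r_[block_max[1:], 0], np.r_[0, block_max[:-1]]))
    ceil = ceil + 1e-12
    block_len = block * dt
    counts = rng.poisson(ceil * block_len)
    total = int(counts.sum())
    if total == 0:
        return np.empty(0)
    block_of = np.repeat(np.arange(nb), counts)
    cand = block_of * block_len + rng.random(total) * block_len
    keep = cand < t_grid[-1]
    cand, block_of = cand[keep], block_of[keep]
    lam = np.interp(cand, t_grid, rate)
    accept = rng.random(cand.size) * ceil[block_of] < lam
    out = np.sort(cand[accept])
    # enforce strictly increasing times at clock resolution
    while out.size > 1 and np.any(np.diff(out) <= 0):
        dup = np.r_[False, np.diff(out) <= 0]
        out[dup] += 1e-6
        out = np.sort(out)
    return out


def simulate_spikes(
    tuning: NeuronTuning,
    trials: TrialTable,
    tracking: TrackingTrace,
    rng: np.random.Generator,
    unit_id: str = "u0",
    choice_side: Sequence | None = None,
    return_rate: bool = False,
):
    """Sample one unit's spike train from its planted rate function."""
    rate = rate_on_grid(tuning, trials, tracking, choice_side)
    times = _thin_poisson(rate, tracking.t_s, rng)
    train = SpikeTrain(unit_id, times)
    return (train, rate) if return_rate else train


def simulate_session(
    config: SynthConfig, keep_rates: bool = True
) -> tuple[Session, GroundTruth]:
    """Simulate a full session: behavior, tracking, and all units' spikes."""
    ss = np.random.SeedSequence(config.seed)
    streams = ss.spawn(1 + len(config.tunings))
    trials, tracking, truth = simulate_behavior(config, np.random.default_rng(streams[0]))
    units = []
    for i, tuning in enumerate(config.tunings):
        uid = f"u{i:03d}"
        train, rate = simulate_spikes(
            tuning, trials, tracking, np.random.default_rng(streams[1 + i]),
            unit_id=uid, choice_side=truth.choice_side, return_rate=True,
        )
        units.append(train)
        if keep_rates:
            truth.rate_samples[uid] = rate
    session = Session(
        trials=trials,
        units=units,
        tracking=tracking,
        meta={"subject": "synthetic", "seed": int(config.seed)},
    )
    return session, truth


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

PRESETS = ("sequences_only", "early_encoding", "choice_encoding", "position_confound", "null")


def _preset_tunings(preset: str, n_units: int, rng: np.random.Generator) -> list[NeuronTuning]:
    baselines = rng.uniform(0.5, 2.5, n_units)  # population mean well under 6 Hz
    sides = np.where(np.arange(n_units) % 2 == 0, "left", "right")
    tunings = []
    for i in range(n_units):
        kw: dict = {"baseline_hz": float(baselines[i])}
        if preset in ("sequences_only", "early_encoding"):
            # peaks tile the 10 s delay uniformly
            kw.update(
                seq_peak_time_s=float(10.0 * (i + 0.5) / n_units),
                seq_width_s=float(rng.uniform(0.4, 0.8)),
                seq_gain_hz=float(rng.uniform(8.0, 15.0)),
            )
        if preset == "early_encoding":
            # stimulus selectivity concentrated in the first ~2 s of the
            # delay (outlasting the run to the port), independent of where
            # the rate peak sits
            kw.update(
                selectivity_gain=float(rng.uniform(2.5, 3.5)),
                selectivity_envelope=(
                    float(rng.uniform(0.0, 0.7)),
                    2.0 + float(rng.uniform(0.0, 0.4)),
                ),
                preferred_side=str(sides[i]),
            )
        if preset == "choice_encoding":
            kw.update(
                selectivity_gain=float(rng.uniform(1.8, 2.5)),
                selectivity_envelope=(0.0, 1.0),
                preferred_side=str(sides[i]),
                choice_selectivity_gain=float(rng.uniform(2.5, 3.5)),
                choice_envelope=(-0.5, 0.5),
                choice_preferred_side=str(sides[i]),
            )
        if preset == "position_confound":
            lever = LEFT_LEVER_XY if sides[i] == "left" else RIGHT_LEVER_XY
            kw.update(
                position_field=PositionField(
                    x_in=float(lever[0] + rng.normal(0, 0.5)),
                    y_in=float(lever[1] - abs(rng.normal(1.0, 0.5))),
                    sigma_in=float(rng.uniform(1.5, 2.5)),
                    gain_hz=float(rng.uniform(6.0, 10.0)),
                )
            )
        tunings.append(NeuronTuning(**kw))
    return tunings


def make_preset_session(
    preset: str,
    seed: int,
    n_units: int = 20,
    n_trials: int = 300,
    delay_set: tuple[float, ...] = (1.0, 5.0, 10.0),
    keep_rates: bool = True,
    **config_overrides,
) -> tuple[Session, GroundTruth]:
    """Build a session with planted dynamics from a named preset.

    Presets
    -------
    ``sequences_only``
        Gaussian rate bumps tiling the 10 s delay; no stimulus selectivity.
    ``early_encoding``
        The same sequence tiling plus multiplicative sample-side selectivity
        confined to the first ~2 s of the delay, so stimulus information and
        rate peaks are planted independently.
    ``choice_encoding``
        Early sample selectivity plus strong choice-side selectivity around
        the choice press (for error-trial decoding tests).
    ``position_confound``
        Tuning only through 2-D position fields near the sample levers, so any
        apparent side selectivity is positional.
    ``null``
        Homogeneous Poisson units.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose one of {PRESETS}")
    ss = np.random.SeedSequence([int(seed), 0xA11CE])
    rng = np.random.default_rng(ss)
    tunings = _preset_tunings(preset, n_units, rng)
    config = SynthConfig(
        n_trials=n_trials, delay_set=delay_set, tunings=tunings, seed=int(seed), **config_overrides
    )
    return simulate_session(config, keep_rates=keep_rates)
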
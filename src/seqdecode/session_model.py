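"""Core session data types, validation, and bundle I/O.

A *session bundle* is a directory holding one recording (or simulated) session
of the delayed non-match-to-position task:

``trials.csv``
    one row per trial with the sample side, delay duration, event timestamps
    (seconds from session start; empty cells for absent events) and outcome.
``units/unit_<id>.csv``
    one single-column file of spike times per unit.
``tracking.csv``
    the head-tracking trace (t, x, y, heading, vx, vy, speed).
``session.yaml``
    chamber geometry and metadata (subject id, rng seed for synthetic data).

Coordinates are inches in a 9.5 x 12 in operant chamber.  The origin is the
left corner of the nose-port wall, with x running across the chamber width
(so the nose-port wall is y = 0 and the lever wall is y = 12).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ValidationError",
    "TrialTable",
    "SpikeTrain",
    "TrackingTrace",
    "Session",
    "read_session",
    "write_session",
    "detect_port_epochs",
    "first_port_arrivals",
    "PORT_RADIUS_IN",
    "CHAMBER_WIDTH_IN",
    "CHAMBER_HEIGHT_IN",
]

#: Default head-distance threshold for "at the nose port" (inches).
PORT_RADIUS_IN = 2.5
CHAMBER_WIDTH_IN = 9.5
CHAMBER_HEIGHT_IN = 12.0

#: Event-timestamp columns of a trial table, in within-trial temporal order.
EVENT_COLUMNS = (
    "t_sample_present",
    "t_sample_press",
    "t_port_on",
    "t_nose_poke",
    "t_choice_press",
    "t_reward_entry",
)

OUTCOMES = ("correct", "error", "sample_omission", "abort")
SIDES = ("left", "right")


class ValidationError(ValueError):
    """A session bundle violated a structural invariant."""


@dataclass
class TrialTable:
    """Per-trial behavioral record.

    Wraps a :class:`pandas.DataFrame` with columns ``trial_index``,
    ``sample_side`` ({left,right}), ``delay_s`` ({1,5,10}), the six event
    timestamps of :data:`EVENT_COLUMNS` (NaN when the event did not occur),
    and ``outcome`` ({correct, error, sample_omission, abort}).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"trial_index", "sample_side", "delay_s", "outcome", *EVENT_COLUMNS}
        missing = required - set(self.df.columns)
        if missing:
            raise ValidationError(f"trial table missing columns: {sorted(missing)}")
        self.df = self.df.reset_index(drop=True)
        # canonical dtypes so CSV round trips compare equal
        self.df["trial_index"] = self.df["trial_index"].astype(int)
        self.df["delay_s"] = self.df["delay_s"].astype(float)
        for col in EVENT_COLUMNS:
            self.df[col] = self.df[col].astype(float)

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TrialTable):
            return NotImplemented
        return self.df[list(self.df.columns)].equals(other.df[list(self.df.columns)])

    def validate(self, frame_tol_s: float = 1 / 30) -> None:
        """Check within-trial event ordering and outcome consistency."""
        for _, row in self.df.iterrows():
            idx = row["trial_index"]
            if row["sample_side"] not in SIDES:
                raise ValidationError(f"trial {idx}: bad sample_side {row['sample_side']!r}")
            if row["outcome"] not in OUTCOMES:
                raise ValidationError(f"trial {idx}: bad outcome {row['outcome']!r}")
            times = [row[c] for c in EVENT_COLUMNS if not _isna(row[c])]
            if any(b <= a for a, b in zip(times, times[1:])):
                raise ValidationError(f"trial {idx}: event timestamps not strictly increasing")
            if not _isna(row["t_sample_press"]) and not _isna(row["t_port_on"]):
                gap = row["t_port_on"] - row["t_sample_press"]
                if abs(gap - row["delay_s"]) > frame_tol_s + 1e-9:
                    raise ValidationError(
                        f"trial {idx}: port onset {gap:.4f}s after press, expected delay "
                        f"{row['delay_s']}s (tolerance {frame_tol_s:.4f}s)"
                    )
            if row["outcome"] in ("correct", "error") and _isna(row["t_choice_press"]):
                raise ValidationError(f"trial {idx}: outcome {row['outcome']} without choice press")
            if row["outcome"] == "sample_omission" and not _isna(row["t_sample_press"]):
                raise ValidationError(f"trial {idx}: sample omission with a sample press")

    def select(
        self,
        outcome: str | Sequence[str] | None = None,
        delay_s: float | Sequence[float] | None = None,
        sample_side: str | None = None,
    ) -> pd.DataFrame:
        """Return the trial rows matching the given condition."""
        df = self.df
        if outcome is not None:
            outcomes = (outcome,) if isinstance(outcome, str) else tuple(outcome)
            df = df[df["outcome"].isin(outcomes)]
        if delay_s is not None:
            delays = (delay_s,) if np.isscalar(delay_s) else tuple(delay_s)
            df = df[df["delay_s"].isin(delays)]
        if sample_side is not None:
            df = df[df["sample_side"] == sample_side]
        return df


@dataclass
class SpikeTrain:
    """Sorted spike timestamps (seconds from session start) of one unit."""

    unit_id: str
    spike_times_s: np.ndarray

    def __post_init__(self) -> None:
        self.spike_times_s = np.asarray(self.spike_times_s, dtype=float)

    def __len__(self) -> int:
        return self.spike_times_s.size

    def validate(self) -> None:
        t = self.spike_times_s
        if t.size and t[0] < 0:
            raise ValidationError(f"unit {self.unit_id}: negative spike time")
        if np.any(np.diff(t) <= 0):
            raise ValidationError(f"unit {self.unit_id}: spike times not strictly increasing")


@dataclass
class TrackingTrace:
    """Uniformly sampled head position/direction/velocity trace."""

    t_s: np.ndarray
    x_in: np.ndarray
    y_in: np.ndarray
    heading_deg: np.ndarray
    vx: np.ndarray
    vy: np.ndarray
    speed: np.ndarray

    def __post_init__(self) -> None:
        for name in ("t_s", "x_in", "y_in", "heading_deg", "vx", "vy", "speed"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))

    @property
    def dt(self) -> float:
        return float(self.t_s[1] - self.t_s[0])

    @property
    def rate_hz(self) -> float:
        return 1.0 / self.dt

    @classmethod
    def from_positions(
        cls, t_s: np.ndarray, x_in: np.ndarray, y_in: np.ndarray, heading_deg: np.ndarray
    ) -> "TrackingTrace":
        """Build a trace, deriving velocities by central finite differences."""
        vx = np.gradient(np.asarray(x_in, float), np.asarray(t_s, float))
        vy = np.gradient(np.asarray(y_in, float), np.asarray(t_s, float))
        return cls(t_s, x_in, y_in, heading_deg, vx, vy, np.hypot(vx, vy))

    def validate(
        self,
        chamber: tuple[float, float] = (CHAMBER_WIDTH_IN, CHAMBER_HEIGHT_IN),
        position_tol_in: float = 1e-6,
    ) -> None:
        dt = np.diff(self.t_s)
        if self.t_s.size < 2:
            raise ValidationError("tracking trace needs at least 2 frames")
        if np.any(np.abs(dt - dt[0]) > 1e-6 * max(1.0, dt[0])):
            raise ValidationError("tracking time grid is not uniform")
        w, h = chamber
        if (
            np.any(self.x_in < -position_tol_in)
            or np.any(self.x_in > w + position_tol_in)
            or np.any(self.y_in < -position_tol_in)
            or np.any(self.y_in > h + position_tol_in)
        ):
            raise ValidationError("tracked positions fall outside the chamber")
        if np.any(self.heading_deg < 0) or np.any(self.heading_deg >= 360):
            raise ValidationError("heading must lie in [0, 360)")


@dataclass
class Session:
    """One recording session: trials, spike trains, tracking, geometry."""

    trials: TrialTable
    units: list[SpikeTrain]
    tracking: TrackingTrace
    chamber: dict = field(
        default_factory=lambda: {"width_in": CHAMBER_WIDTH_IN, "height_in": CHAMBER_HEIGHT_IN}
    )
    meta: dict = field(default_factory=dict)

    @property
    def duration_s(self) -> float:
        return float(self.tracking.t_s[-1])

    @property
    def unit_ids(self) -> list[str]:
        return [u.unit_id for u in self.units]

    def unit(self, unit_id: str) -> SpikeTrain:
        for u in self.units:
            if u.unit_id == unit_id:
                return u
        raise KeyError(unit_id)

    def validate(self) -> None:
        if not self.units:
            raise ValidationError("session has no units")
        self.tracking.validate((self.chamber["width_in"], self.chamber["height_in"]))
        self.trials.validate(frame_tol_s=self.tracking.dt)
        t0, t1 = self.tracking.t_s[0], self.tracking.t_s[-1]
        ev = self.trials.df[list(EVENT_COLUMNS)].to_numpy(dtype=float)
        finite = ev[np.isfinite(ev)]
        if finite.size and (finite.min() < t0 - 1e-9 or finite.max() > t1 + 1e-9):
            raise ValidationError("trial events fall outside the tracking time range")
        for u in self.units:
            u.validate()


def _isna(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x)) or pd.isna(x)


# ---------------------------------------------------------------------------
# Bundle I/O
# ---------------------------------------------------------------------------

_TRACKING_COLUMNS = ("t", "x", "y", "heading", "vx", "vy", "speed")


def write_session(session: Session, path: str | Path) -> None:
    """Write ``session`` as a bundle directory readable by :func:`read_session`.

    Numeric fields are written with 17 significant digits so the round trip
    is lossless at double precision.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    session.trials.df.to_csv(path / "trials.csv", index=False, float_format="%.17g")
    tr = session.tracking
    pd.DataFrame(
        dict(zip(_TRACKING_COLUMNS, (tr.t_s, tr.x_in, tr.y_in, tr.heading_deg, tr.vx, tr.vy, tr.speed)))
    ).to_csv(path / "tracking.csv", index=False, float_format="%.17g")
    units_dir = path / "units"
    units_dir.mkdir(exist_ok=True)
    for u in session.units:
        pd.DataFrame({"spike_time_s": u.spike_times_s}).to_csv(
            units_dir / f"unit_{u.unit_id}.csv", index=False, float_format="%.17g"
        )
    with open(path / "session.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "chamber": session.chamber,
                "meta": session.meta,
                "unit_ids": session.unit_ids,
            },
            fh,
        )


def read_session(path: str | Path, validate: bool = True) -> Session:
    """Read and validate a session bundle directory."""
    path = Path(path)
    try:
        with open(path / "session.yaml") as fh:
            head = yaml.safe_load(fh)
    except FileNotFoundError as exc:
        raise ValidationError(f"{path}: missing session.yaml") from exc
    except yaml.YAMLError as exc:
        raise ValidationError(f"{path / 'session.yaml'}: cannot parse ({exc})") from exc
    trials_df = _read_csv(path / "trials.csv")
    for col in ("trial_index", "sample_side", "delay_s", "outcome", *EVENT_COLUMNS):
        if col not in trials_df.columns:
            raise ValidationError(f"{path / 'trials.csv'}: missing column {col!r}")
    for col in EVENT_COLUMNS:
        trials_df[col] = pd.to_numeric(trials_df[col], errors="coerce")
    track_df = _read_csv(path / "tracking.csv")
    for col in _TRACKING_COLUMNS:
        if col not in track_df.columns:
            raise ValidationError(f"{path / 'tracking.csv'}: missing column {col!r}")
    tracking = TrackingTrace(*(track_df[c].to_numpy(float) for c in _TRACKING_COLUMNS))
    units = []
    for unit_id in head.get("unit_ids", []):
        f = path / "units" / f"unit_{unit_id}.csv"
        df = _read_csv(f)
        if "spike_time_s" not in df.columns:
            raise ValidationError(f"{f}: missing column 'spike_time_s'")
        units.append(SpikeTrain(str(unit_id), df["spike_time_s"].to_numpy(float)))
    session = Session(
        trials=TrialTable(trials_df),
        units=units,
        tracking=tracking,
        chamber=head.get("chamber", {"width_in": CHAMBER_WIDTH_IN, "height_in": CHAMBER_HEIGHT_IN}),
        meta=head.get("meta", {}) or {},
    )
    if validate:
        session.validate()
    return session


def _read_csv(f: Path) -> pd.DataFrame:
    try:
        return pd.read_csv(f, float_precision="round_trip")
    except FileNotFoundError as exc:
        raise ValidationError(f"missing bundle file {f}") from exc
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValidationError(f"{f}: cannot parse ({exc})") from exc


# ---------------------------------------------------------------------------
# Nose-port localization
# ---------------------------------------------------------------------------

def detect_port_epochs(
    tracking: TrackingTrace,
    poke_times: Sequence[float],
    radius_in: float = PORT_RADIUS_IN,
) -> np.ndarray:
    """Find "at the nose port" intervals from head tracking.

    The port reference point is the per-axis median of head positions at the
    nose-poke times; every maximal run of frames whose head position lies
    within ``radius_in`` (Euclidean) of that point is one epoch.

    Returns an (n, 2) array of half-open ``[start, end)`` times.  Epoch edges
    lie on the frame grid; the final frame of a run contributes one frame
    duration.
    """
    poke_times = np.asarray(list(poke_times), dtype=float)
    poke_times = poke_times[np.isfinite(poke_times)]
    in_range = poke_times[(poke_times >= tracking.t_s[0]) & (poke_times <= tracking.t_s[-1])]
    if in_range.size == 0:
        raise ValidationError("cannot locate port: no poke time with tracking coverage")
    idx = np.clip(np.round((in_range - tracking.t_s[0]) / tracking.dt).astype(int), 0, tracking.t_s.size - 1)
    ref = np.array([np.median(tracking.x_in[idx]), np.median(tracking.y_in[idx])])
    dist = np.hypot(tracking.x_in - ref[0], tracking.y_in - ref[1])
    at_port = dist <= radius_in
    edges = np.diff(at_port.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if at_port[0]:
        starts = np.r_[0, starts]
    if at_port[-1]:
        ends = np.r_[ends, at_port.size]
    t0, dt = tracking.t_s[0], tracking.dt
    return np.column_stack([t0 + starts * dt, t0 + ends * dt])


def first_port_arrivals(epochs: np.ndarray, press_times: Sequence[float]) -> np.ndarray:
    """First port-epoch start strictly after each sample press (NaN if none)."""
    starts = np.asarray(epochs)[:, 0]
    out = np.full(len(press_times), np.nan)
    for i, tp in enumerate(press_times):
        if not np.isfinite(tp):
            continue
        later = starts[starts > tp]
        if later.size:
            out[i] = later[0]
    return out
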
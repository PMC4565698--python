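"""Event-log ingestion, filtering, windowing, and aggression matrices.

The raw observable is a timestamped dyadic "aggressive win": an actor
displaces a target from its perch. Wins are logged as ``(time, actor,
target)`` rows; everything downstream (power scores, null models, chain
motifs) is computed from the integer win-count matrix ``d[i, j]`` — the
number of wins individual *i* scored against individual *j* inside an
observation window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AggressionEventLog",
    "AggressionMatrix",
    "read_event_log",
    "event_log_from_frame",
    "apply_win_cooldown",
    "split_windows",
    "exclude_individuals",
    "build_matrix",
    "network_density",
]

SECONDS_PER_DAY = 86_400.0
MINUTES_PER_DAY = 1_440.0


@dataclass(frozen=True)
class AggressionEventLog:
    """An ordered sequence of aggressive-win events on a fixed roster.

    Parameters
    ----------
    events
        DataFrame with columns ``time`` (seconds since observation start,
        non-decreasing), ``actor`` and ``target`` (roster ids).
    roster
        Stable, ordered tuple of individual ids. Matrix rows/columns and
        every derived statistic follow this order.
    t_obs_minutes
        Total observation time T_obs in minutes. Must cover every event.
    label
        Free-form window label (e.g. ``"Q1"``).
    start_day, end_day
        Half-open day interval this log covers, in days since study start.
    """

    events: pd.DataFrame
    roster: tuple[str, ...]
    t_obs_minutes: float
    label: str = ""
    start_day: float = 0.0
    end_day: float | None = None

    def __post_init__(self) -> None:
        ev = self.events
        required = {"time", "actor", "target"}
        if not required.issubset(ev.columns):
            raise ValueError(f"event frame must have columns {sorted(required)}")
        if len(set(self.roster)) != len(self.roster):
            raise ValueError("roster ids must be unique")
        if self.t_obs_minutes <= 0:
            raise ValueError("t_obs_minutes must be positive")
        if len(ev):
            t = ev["time"].to_numpy(dtype=float)
            if not np.all(np.isfinite(t)):
                raise ValueError("event times must be finite")
            if np.any(np.diff(t) < 0):
                raise ValueError("events must be sorted by time")
            if t[-1] > self.t_obs_minutes * 60.0 + 1e-9:
                raise ValueError("t_obs_minutes shorter than the event record")
            known = set(self.roster)
            ids = set(ev["actor"]) | set(ev["target"])
            if not ids.issubset(known):
                raise ValueError(f"ids outside roster: {sorted(ids - known)}")
            if (ev["actor"] == ev["target"]).any():
                bad = ev.index[ev["actor"] == ev["target"]].tolist()
                raise ValueError(f"self-directed events at rows {bad}")

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def n_individuals(self) -> int:
        return len(self.roster)

    @property
    def duration_days(self) -> float:
        return self.t_obs_minutes / MINUTES_PER_DAY


def _coerce_times(raw: pd.Series, path: str) -> pd.Series:
    """Accept float seconds or ISO-8601 timestamps; return float seconds."""
    numeric = pd.to_numeric(raw, errors="coerce")
    if numeric.notna().all():
        return numeric.astype(float)
    stamps = pd.to_datetime(raw, errors="coerce", format="ISO8601")
    if stamps.isna().any():
        bad = raw.index[stamps.isna() & numeric.isna()].tolist()
        raise ValueError(f"{path}: unparseable time values at rows {bad}")
    return (stamps - stamps.min()).dt.total_seconds().astype(float)


def event_log_from_frame(
    frame: pd.DataFrame,
    roster: Sequence[str] | None = None,
    t_obs_minutes: float | None = None,
    label: str = "",
) -> AggressionEventLog:
    """Build a validated log from an in-memory ``time,actor,target`` frame.

    Malformed rows (missing fields, actor == target, ids outside a supplied
    roster) raise ``ValueError`` naming the offending row numbers. If
    ``t_obs_minutes`` is omitted the observation time defaults to the whole
    days needed to cover the record (at least one day).
    """
    missing = {"time", "actor", "target"} - set(frame.columns)
    if missing:
        raise ValueError(f"missing required columns: {sorted(missing)}")
    ev = frame.loc[:, ["time", "actor", "target"]].copy()
    ev["actor"] = ev["actor"].astype(str).str.strip()
    ev["target"] = ev["target"].astype(str).str.strip()

    null_rows = ev.index[ev.isna().any(axis=1) | (ev["actor"] == "") | (ev["target"] == "")]
    if len(null_rows):
        raise ValueError(f"malformed rows (empty fields): {null_rows.tolist()}")
    ev["time"] = _coerce_times(ev["time"], "event log")

    selfed = ev.index[ev["actor"] == ev["target"]]
    if len(selfed):
        raise ValueError(f"actor == target at rows {selfed.tolist()}")

    if roster is None:
        roster = tuple(sorted(set(ev["actor"]) | set(ev["target"])))
    else:
        roster = tuple(str(r) for r in roster)
        known = set(roster)
        bad = ev.index[~(ev["actor"].isin(known) & ev["target"].isin(known))]
        if len(bad):
            raise ValueError(f"unknown ids at rows {bad.tolist()}")

    ev = ev.sort_values("time", kind="stable").reset_index(drop=True)
    if t_obs_minutes is None:
        max_day = float(ev["time"].max()) / SECONDS_PER_DAY if len(ev) else 0.0
        t_obs_minutes = max(1.0, math.ceil(max_day - 1e-12)) * MINUTES_PER_DAY
    return AggressionEventLog(ev, roster, float(t_obs_minutes), label=label)


def read_event_log(
    path,
    roster: Sequence[str] | None = None,
    t_obs_minutes: float | None = None,
) -> AggressionEventLog:
    """Read a ``time,actor,target`` CSV into a validated event log.

    ``time`` may be float seconds since observation start or ISO-8601
    timestamps (converted to seconds from the earliest stamp). Events are
    returned sorted ascending by time; the roster is inferred from the data
    (sorted ids) when not supplied.
    """
    frame = pd.read_csv(path, dtype={"actor": str, "target": str})
    return event_log_from_frame(frame, roster=roster, t_obs_minutes=t_obs_minutes)


def apply_win_cooldown(
    log: AggressionEventLog, cooldown_seconds: float = 60.0
) -> AggressionEventLog:
    """Collapse sub-attack barrages into single wins per actor→target pair.

    A win A→B is retained only if at least ``cooldown_seconds`` have elapsed
    since the previously *retained* A→B win; the first event of each ordered
    pair is always retained. The clock resets from the last retained event,
    so a continuous barrage yields one win per cooldown period rather than a
    single win forever. Distinct ordered pairs never interact.
    """
    if cooldown_seconds <= 0:
        raise ValueError("cooldown_seconds must be positive")
    ev = log.events
    if not len(ev):
        return log
    keep = np.zeros(len(ev), dtype=bool)
    times = ev["time"].to_numpy(dtype=float)
    for _, idx in ev.groupby(["actor", "target"], sort=False).indices.items():
        last = -np.inf
        for i in idx:
            if times[i] - last >= cooldown_seconds:
                keep[i] = True
                last = times[i]
    return replace(log, events=ev.loc[keep].reset_index(drop=True))


def split_windows(
    log: AggressionEventLog, window_days: float = 6.0, force: bool = False
) -> list[AggressionEventLog]:
    """Partition a log into consecutive observation windows of equal length.

    Windows are half-open ``[start, end)`` in event time — an event at
    exactly a boundary belongs to the later window. The study duration must
    be an exact multiple of ``window_days`` unless ``force`` is set, in
    which case a short final window is allowed. Per-window T_obs is
    proportional to window length.
    """
    if window_days <= 0:
        raise ValueError("window_days must be positive")
    duration = log.duration_days
    n_exact = duration / window_days
    if abs(n_exact - round(n_exact)) > 1e-9 and not force:
        raise ValueError(
            f"study duration {duration:g} d is not a multiple of "
            f"window_days={window_days:g}; pass force=True to allow a short "
            "final window"
        )
    n_windows = int(math.ceil(n_exact - 1e-9))
    times = log.events["time"].to_numpy(dtype=float)
    out = []
    for w in range(n_windows):
        start, end = w * window_days, min((w + 1) * window_days, duration)
        lo, hi = start * SECONDS_PER_DAY, end * SECONDS_PER_DAY
        if w == n_windows - 1:
            mask = (times >= lo) & (times <= hi + 1e-9)  # close the study end
        else:
            mask = (times >= lo) & (times < hi)
        shifted = log.events.loc[mask].reset_index(drop=True).copy()
        shifted["time"] = shifted["time"] - lo
        out.append(
            AggressionEventLog(
                shifted,
                log.roster,
                (end - start) * MINUTES_PER_DAY,
                label=f"Q{w + 1}",
                start_day=start,
                end_day=end,
            )
        )
    return out


def exclude_individuals(
    log: AggressionEventLog, ids: Sequence[str]
) -> AggressionEventLog:
    """Drop individuals from the roster and every event they touch.

    Used for anomalous individuals whose incoming aggression is reactive
    rather than strategic; T_obs is unchanged (observation time does not
    shrink because a bird was censored).
    """
    ids = [str(i) for i in ids]
    unknown = set(ids) - set(log.roster)
    if unknown:
        raise ValueError(f"cannot exclude unknown ids: {sorted(unknown)}")
    if not ids:
        return log
    dropped = set(ids)
    ev = log.events
    mask = ~(ev["actor"].isin(dropped) | ev["target"].isin(dropped))
    roster = tuple(r for r in log.roster if r not in dropped)
    return replace(log, events=ev.loc[mask].reset_index(drop=True), roster=roster)


@dataclass(frozen=True)
class AggressionMatrix:
    """Integer win-count matrix ``d[i, j]`` on a fixed roster order."""

    counts: np.ndarray
    roster: tuple[str, ...]
    window_label: str = ""
    t_obs_minutes: float = field(default=0.0, compare=False)

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("counts must be a square matrix")
        if c.shape[0] != len(self.roster):
            raise ValueError("counts shape does not match roster length")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        if np.any(np.diag(c) != 0):
            raise ValueError("diagonal (self-aggression) must be zero")
        object.__setattr__(self, "counts", c)

    @property
    def n(self) -> int:
        return len(self.roster)

    @property
    def total_events(self) -> int:
        return int(self.counts.sum())

    def index_of(self, individual: str) -> int:
        return self.roster.index(individual)


def build_matrix(log: AggressionEventLog) -> AggressionMatrix:
    """Tally the event log into the win-count matrix ``d``."""
    if not log.roster:
        raise ValueError("roster is empty")
    n = len(log.roster)
    pos = {ind: i for i, ind in enumerate(log.roster)}
    counts = np.zeros((n, n), dtype=np.int64)
    if len(log.events):
        ai = log.events["actor"].map(pos).to_numpy()
        ti = log.events["target"].map(pos).to_numpy()
        np.add.at(counts, (ai, ti), 1)
    return AggressionMatrix(
        counts, log.roster, window_label=log.label, t_obs_minutes=log.t_obs_minutes
    )


def network_density(m: AggressionMatrix, directed: bool = True) -> float:
    """Fraction of possible pairs with at least one win recorded.

    ``directed=True`` (default) counts ordered off-diagonal pairs with
    ``d[i, j] > 0``; ``directed=False`` counts unordered dyads with
    aggression in either direction.
    """
    n = m.n
    if n < 2:
        raise ValueError("density needs at least two individuals")
    c = m.counts
    if directed:
        return float((c > 0).sum() / (n * (n - 1)))
    either = (c > 0) | (c.T > 0)
    iu = np.triu_indices(n, k=1)
    return float(either[iu].sum() / (n * (n - 1) / 2))
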
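"""Clapping-bout data model, file I/O, and likelihood-ready observations.

An applause bout is represented as one :class:`ClapRecord` per audience
member: when they first clapped (``start_time``), when they last clapped
(``stop_time``), the individual clap times in between, and where they sat.
All times are in seconds relative to the first clap of the bout, which is
the natural time origin because the end of the stimulus itself cannot be
pinned down precisely.

Two observation sets feed the hazard likelihoods:

* *starting* observations — one per susceptible individual per time frame
  of length ``dt``, labelled ``started`` / ``not_started``, carrying the
  audience composition at the frame start;
* *stopping* observations — one per clap per individual, labelled
  ``stopped`` / ``continued``, carrying the stopped fraction just before
  that clap.

Fractions use the full audience size ``N`` as denominator, matching the
S/I/R proportions of the stochastic simulator.  Simultaneous events are
ordered deterministically by ``(time, individual_id)``.
"""

from __future__ import annotations

import bisect
import csv
import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ClapRecord",
    "Bout",
    "AudienceState",
    "StartObservation",
    "StopObservation",
    "read_bouts",
    "write_bouts",
    "audience_state",
    "audience_trajectory",
    "fractions_on_grid",
    "make_start_observations",
    "make_stop_observations",
]

CSV_HEADER = [
    "group_id",
    "talk_id",
    "individual_id",
    "seat_row",
    "seat_col",
    "start_time",
    "stop_time",
    "clap_times",
]

_TOL = 1e-9


class ValidationError(ValueError):
    """Raised when a record or bout violates a structural invariant."""


@dataclass(frozen=True)
class ClapRecord:
    """One individual's participation in one applause bout.

    ``start_time is None`` marks a non-starter: someone who never clapped.
    Non-starters carry no stop time and no clap times.  For starters,
    ``clap_times`` (when present) is strictly increasing, begins at
    ``start_time`` and ends at ``stop_time``.  When individual clap times
    were not coded, ``n_claps`` together with a mean clap interval allows
    reconstruction (see :meth:`with_reconstructed_claps`).
    """

    group_id: str
    talk_id: int
    individual_id: str
    seat_row: int
    seat_col: int
    start_time: float | None
    stop_time: float | None = None
    clap_times: tuple[float, ...] | None = None
    n_claps: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "group_id", str(self.group_id))
        object.__setattr__(self, "individual_id", str(self.individual_id))
        object.__setattr__(self, "talk_id", int(self.talk_id))
        if self.clap_times is not None:
            object.__setattr__(self, "clap_times", tuple(float(t) for t in self.clap_times))
        self.validate()

    @property
    def is_starter(self) -> bool:
        return self.start_time is not None

    def validate(self) -> None:
        tag = f"record ({self.group_id}, talk {self.talk_id}, {self.individual_id})"
        if self.seat_row < 0 or self.seat_col < 0:
            raise ValidationError(f"{tag}: negative seat coordinates")
        if self.start_time is None:
            if self.stop_time is not None or self.clap_times:
                raise ValidationError(f"{tag}: non-starter must have no stop_time/clap_times")
            return
        if self.stop_time is None:
            raise ValidationError(f"{tag}: starter lacks stop_time")
        if self.stop_time < self.start_time - _TOL:
            raise ValidationError(f"{tag}: stop_time {self.stop_time} < start_time {self.start_time}")
        if self.clap_times is not None:
            ct = self.clap_times
            if len(ct) == 0:
                raise ValidationError(f"{tag}: empty clap_times for a starter")
            if any(b - a <= 0 for a, b in zip(ct, ct[1:])):
                raise ValidationError(f"{tag}: clap_times not strictly increasing")
            if abs(ct[0] - self.start_time) > _TOL or abs(ct[-1] - self.stop_time) > _TOL:
                raise ValidationError(
                    f"{tag}: clap_times must span [start_time, stop_time] "
                    f"(got [{ct[0]}, {ct[-1]}] vs [{self.start_time}, {self.stop_time}])"
                )

    def with_reconstructed_claps(self, mean_interval: float = 0.28) -> "ClapRecord":
        """Fill in ``clap_times`` from the clap count and a mean interval.

        Claps are spread uniformly over ``[start_time, stop_time]``.  If
        ``n_claps`` is unset it is inferred from the clapping duration and
        ``mean_interval`` (at least one clap).
        """
        if not self.is_starter or self.clap_times is not None:
            return self
        duration = self.stop_time - self.start_time
        n = self.n_claps if self.n_claps is not None else int(round(duration / mean_interval)) + 1
        n = max(n, 1)
        if n == 1:
            if duration > _TOL:
                raise ValidationError(
                    f"record {self.individual_id}: one clap but stop_time > start_time"
                )
            times = (self.start_time,)
        else:
            times = tuple(np.linspace(self.start_time, self.stop_time, n))
        return replace(self, clap_times=times, n_claps=n)


@dataclass(frozen=True)
class Bout:
    """All records of one (group, talk) applause bout.

    The time origin is the bout's first clap: at least one record starts
    at t=0.  ``latency`` optionally records the absolute delay from the
    end of the stimulus to that first clap.
    """

    records: tuple[ClapRecord, ...]
    latency: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        if not self.records:
            raise ValidationError("empty bout")
        keys = {(r.group_id, r.talk_id) for r in self.records}
        if len(keys) != 1:
            raise ValidationError(f"bout mixes (group, talk) keys: {sorted(keys)}")
        ids = [r.individual_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate individual_id within bout")
        starts = [r.start_time for r in self.records if r.is_starter]
        if not starts:
            raise ValidationError("bout has no starters")
        if min(starts) > _TOL or min(starts) < -_TOL:
            raise ValidationError("bout time origin must be the first clap (min start_time == 0)")

    @property
    def group_id(self) -> str:
        return self.records[0].group_id

    @property
    def talk_id(self) -> int:
        return self.records[0].talk_id

    @property
    def n(self) -> int:
        """Audience size N (starters plus non-starters)."""
        return len(self.records)

    @property
    def starters(self) -> tuple[ClapRecord, ...]:
        return tuple(r for r in self.records if r.is_starter)

    @property
    def end_time(self) -> float:
        stops = [r.stop_time for r in self.records if r.stop_time is not None]
        return max(stops) if stops else max(r.start_time for r in self.starters)

    @property
    def first_stop_time(self) -> float | None:
        stops = [r.stop_time for r in self.records if r.stop_time is not None]
        return min(stops) if stops else None

    def record_of(self, individual_id: str) -> ClapRecord:
        for r in self.records:
            if r.individual_id == individual_id:
                return r
        raise KeyError(individual_id)

    def neighbours(self, include_diagonals: bool = False) -> dict[str, tuple[str, ...]]:
        """Seat-adjacency map: left/right/front/back (optionally diagonals)."""
        by_seat = {(r.seat_row, r.seat_col): r.individual_id for r in self.records}
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
        if include_diagonals:
            offsets += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
        out: dict[str, tuple[str, ...]] = {}
        for (row, col), iid in by_seat.items():
            out[iid] = tuple(
                by_seat[(row + dr, col + dc)]
                for dr, dc in offsets
                if (row + dr, col + dc) in by_seat
            )
        return out

    def with_reconstructed_claps(self, mean_interval: float = 0.28) -> "Bout":
        return Bout(
            tuple(r.with_reconstructed_claps(mean_interval) for r in self.records),
            latency=self.latency,
        )


@dataclass(frozen=True)
class AudienceState:
    """S/I/R composition of the audience at one instant.

    ``rho_clapping`` is the fraction (of the full audience N) that has
    started clapping, whether or not they have since stopped — the
    "already infected" I+R proportion.  ``rho_stopped`` is the fraction
    that has started and then stopped (R).  Non-starters are counted in
    the denominator but never in either numerator.
    """

    time: float
    rho_clapping: float
    rho_stopped: float
    phase: Mapping[str, str]  # individual_id -> "S" | "I" | "R"
    neighbour_clapping: Mapping[str, float]
    neighbour_stopped: Mapping[str, float]

    def __post_init__(self) -> None:
        if not (-_TOL <= self.rho_stopped <= self.rho_clapping + _TOL <= 1 + 2 * _TOL):
            raise ValidationError(
                f"invalid fractions at t={self.time}: "
                f"rho_stopped={self.rho_stopped}, rho_clapping={self.rho_clapping}"
            )


@dataclass(frozen=True)
class StartObservation:
    """One susceptible-individual frame [t0, t1) for the starting models."""

    individual_id: str
    t0: float
    t1: float
    rho_clapping: float
    neighbour_fraction: float
    outcome: str  # "started" | "not_started"

    @property
    def started(self) -> bool:
        return self.outcome == "started"


@dataclass(frozen=True)
class StopObservation:
    """One clap of one individual for the stopping models.

    ``rho_stopped`` and ``neighbour_fraction`` describe the audience just
    *before* this clap (ties broken by individual id), so an individual's
    own stop never feeds back into its final observation.
    """

    individual_id: str
    time: float
    n_claps: int
    rho_stopped: float
    neighbour_fraction: float
    outcome: str  # "stopped" | "continued"

    @property
    def stopped(self) -> bool:
        return self.outcome == "stopped"


# ---------------------------------------------------------------------------
# I/O


def _fmt(x: float | None) -> str:
    return "" if x is None else format(float(x), ".17g")


def _record_to_row(r: ClapRecord) -> list[str]:
    claps = ";".join(format(t, ".17g") for t in r.clap_times) if r.clap_times else ""
    return [
        r.group_id,
        str(r.talk_id),
        r.individual_id,
        str(r.seat_row),
        str(r.seat_col),
        _fmt(r.start_time),
        _fmt(r.stop_time),
        claps,
    ]


def _row_to_record(row: Mapping[str, str], where: str) -> ClapRecord:
    try:
        start = row["start_time"].strip()
        stop = row["stop_time"].strip()
        claps = row.get("clap_times", "").strip()
        return ClapRecord(
            group_id=row["group_id"],
            talk_id=int(row["talk_id"]),
            individual_id=row["individual_id"],
            seat_row=int(row["seat_row"]),
            seat_col=int(row["seat_col"]),
            start_time=float(start) if start else None,
            stop_time=float(stop) if stop else None,
            clap_times=tuple(float(t) for t in claps.split(";")) if claps else None,
        )
    except ValidationError:
        raise
    except (KeyError, ValueError) as exc:
        raise ValidationError(f"malformed {where}: {exc}") from exc


def _group_records(records: Iterable[ClapRecord], latencies=None) -> list[Bout]:
    grouped: dict[tuple[str, int], list[ClapRecord]] = {}
    for r in records:
        grouped.setdefault((r.group_id, r.talk_id), []).append(r)
    bouts = []
    for key in sorted(grouped):
        recs = grouped[key]
        # shift time origin so the earliest start is exactly 0
        t0 = min(r.start_time for r in recs if r.is_starter)
        shifted = []
        for r in recs:
            if r.is_starter:
                r = replace(
                    r,
                    start_time=r.start_time - t0,
                    stop_time=r.stop_time - t0,
                    clap_times=tuple(t - t0 for t in r.clap_times) if r.clap_times else None,
                )
            shifted.append(r)
        lat = latencies.get(key) if latencies else None
        bouts.append(Bout(tuple(shifted), latency=lat))
    return bouts


def read_bouts(path: str | Path, fmt: str | None = None) -> list[Bout]:
    """Read bouts from CSV or JSON (format inferred from the suffix).

    Each bout's time origin is shifted so its earliest start time is 0.
    Malformed rows raise :class:`ValidationError` naming the record.
    """
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt == "csv":
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            records = [
                _row_to_record(row, f"row {i + 2} of {path.name}")
                for i, row in enumerate(reader)
            ]
        if not records:
            raise ValidationError(f"{path}: no records")
        return _group_records(records)
    if fmt == "json":
        payload = json.loads(Path(path).read_text())
        records, latencies = [], {}
        for bout in payload["bouts"]:
            for rec in bout["records"]:
                rec = {k: "" if v is None else str(v) for k, v in rec.items()}
                if isinstance(rec.get("clap_times"), str) and rec["clap_times"].startswith("["):
                    rec["clap_times"] = ";".join(
                        str(t) for t in json.loads(rec["clap_times"])
                    )
                records.append(_row_to_record(rec, f"record in {path.name}"))
            if bout.get("latency") is not None:
                key = (str(bout["records"][0]["group_id"]), int(bout["records"][0]["talk_id"]))
                latencies[key] = float(bout["latency"])
        return _group_records(records, latencies)
    raise ValueError(f"unknown format {fmt!r} (expected csv or json)")


def write_bouts(bouts: Sequence[Bout], path: str | Path, fmt: str | None = None) -> Path:
    """Write bouts in the CSV or JSON schema (CSV drops bout latency)."""
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(CSV_HEADER)
            for bout in bouts:
                for r in bout.records:
                    writer.writerow(_record_to_row(r))
        return path
    if fmt == "json":
        payload = {
            "bouts": [
                {
                    "latency": bout.latency,
                    "records": [
                        {
                            "group_id": r.group_id,
                            "talk_id": r.talk_id,
                            "individual_id": r.individual_id,
                            "seat_row": r.seat_row,
                            "seat_col": r.seat_col,
                            "start_time": r.start_time,
                            "stop_time": r.stop_time,
                            "clap_times": ";".join(format(t, ".17g") for t in r.clap_times)
                            if r.clap_times
                            else "",
                        }
                        for r in bout.records
                    ],
                }
                for bout in bouts
            ]
        }
        path.write_text(json.dumps(payload, indent=1))
        return path
    raise ValueError(f"unknown format {fmt!r} (expected csv or json)")


# ---------------------------------------------------------------------------
# Audience state


def _sorted_events(bout: Bout):
    starts = sorted(
        (r.start_time, r.individual_id) for r in bout.records if r.is_starter
    )
    stops = sorted(
        (r.stop_time, r.individual_id) for r in bout.records if r.stop_time is not None
    )
    return starts, stops


def audience_state(
    bout: Bout, t: float, include_diagonals: bool = False
) -> AudienceState:
    """Right-continuous audience composition at time ``t``.

    Events occurring exactly at ``t`` are counted as having happened.
    """
    phase: dict[str, str] = {}
    n_started = n_stopped = 0
    for r in bout.records:
        if r.is_starter and r.start_time <= t + _TOL:
            if r.stop_time <= t + _TOL:
                phase[r.individual_id] = "R"
                n_stopped += 1
            else:
                phase[r.individual_id] = "I"
            n_started += 1
        else:
            phase[r.individual_id] = "S"
    nbrs = bout.neighbours(include_diagonals)
    neigh_clap = {
        iid: (
            sum(phase[j] != "S" for j in js) / len(js) if js else 0.0
        )
        for iid, js in nbrs.items()
    }
    neigh_stop = {
        iid: (sum(phase[j] == "R" for j in js) / len(js) if js else 0.0)
        for iid, js in nbrs.items()
    }
    return AudienceState(
        time=t,
        rho_clapping=n_started / bout.n,
        rho_stopped=n_stopped / bout.n,
        phase=phase,
        neighbour_clapping=neigh_clap,
        neighbour_stopped=neigh_stop,
    )


def audience_trajectory(
    bout: Bout, time_grid: Sequence[float], include_diagonals: bool = False
) -> list[AudienceState]:
    """Audience states along ``time_grid`` (stepwise constant between events)."""
    if bout is None or not bout.records:
        raise ValidationError("empty bout")
    return [audience_state(bout, float(t), include_diagonals) for t in time_grid]


def fractions_on_grid(
    bout: Bout, time_grid: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised (started, stopped) fractions on a time grid.

    Right-continuous step functions jumping exactly at start/stop events;
    denominators are the full audience size.
    """
    grid = np.asarray(time_grid, dtype=float)
    starts = np.sort([r.start_time for r in bout.records if r.is_starter])
    stops = np.sort([r.stop_time for r in bout.records if r.stop_time is not None])
    started = np.searchsorted(starts, grid + _TOL, side="left") / bout.n
    stopped = np.searchsorted(stops, grid + _TOL, side="left") / bout.n
    return started, stopped


# ---------------------------------------------------------------------------
# Observation construction


def make_start_observations(
    bout: Bout, dt: float = 0.1, include_diagonals: bool = False
) -> list[StartObservation]:
    """Per-frame starting observations for every non-initiator individual.

    Frames of length ``dt`` run from t=0 until the individual's start (for
    starters) or until the bout's end (non-starters).  Individuals who
    start at t=0 set the time origin and are conditioned on, contributing
    no observations.  Frame-start state excludes the focal individual from
    the clapping count (the focal is susceptible by construction).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    starts_sorted = np.sort([r.start_time for r in bout.records if r.is_starter])
    nbrs = bout.neighbours(include_diagonals)
    start_by_id = {
        r.individual_id: r.start_time for r in bout.records if r.is_starter
    }
    end = bout.end_time
    n = bout.n
    out: list[StartObservation] = []
    for r in bout.records:
        if r.is_starter and r.start_time <= _TOL:
            continue  # initiator: sets the clock, not modelled
        if r.is_starter:
            k_last = int(math.floor((r.start_time - _TOL) / dt))
            n_frames = k_last + 1
        else:
            n_frames = int(math.ceil((end - _TOL) / dt)) if end > _TOL else 1
        js = nbrs.get(r.individual_id, ())
        nbr_starts = np.sort([start_by_id[j] for j in js if j in start_by_id])
        n_js = len(js)
        for k in range(n_frames):
            t0 = k * dt
            n_clap = int(np.searchsorted(starts_sorted, t0 + _TOL, side="left"))
            if r.is_starter and r.start_time <= t0 + _TOL:
                n_clap -= 1  # never count the focal individual itself
            nb = (
                int(np.searchsorted(nbr_starts, t0 + _TOL, side="left")) / n_js
                if n_js
                else 0.0
            )
            started = r.is_starter and k == n_frames - 1
            out.append(
                StartObservation(
                    individual_id=r.individual_id,
                    t0=t0,
                    t1=t0 + dt,
                    rho_clapping=n_clap / n,
                    neighbour_fraction=nb,
                    outcome="started" if started else "not_started",
                )
            )
    return out


def make_stop_observations(
    bout: Bout,
    restrict_after_first_stop: bool = False,
    include_diagonals: bool = False,
) -> list[StopObservation]:
    """Per-clap stopping observations for every starter.

    State is taken strictly before each clap, with simultaneous events
    ordered by ``(time, individual_id)``.  With
    ``restrict_after_first_stop`` only observations whose pre-event
    stopped fraction is positive are kept — i.e. the analysis restricted
    to claps after at least one audience member has stopped.
    """
    missing = [
        r.individual_id for r in bout.records if r.is_starter and r.clap_times is None
    ]
    if missing:
        raise ValidationError(
            f"records {missing} lack clap_times; call "
            "Bout.with_reconstructed_claps(mean_interval) to rebuild them "
            "from clap counts before making stop observations"
        )
    stops_sorted = sorted(
        (r.stop_time, r.individual_id) for r in bout.records if r.stop_time is not None
    )
    stop_by_id = {
        r.individual_id: r.stop_time for r in bout.records if r.stop_time is not None
    }
    nbrs = bout.neighbours(include_diagonals)
    n = bout.n
    out: list[StopObservation] = []
    for r in bout.records:
        if not r.is_starter:
            continue
        js = nbrs.get(r.individual_id, ())
        nbr_stops = sorted(
            (stop_by_id[j], j) for j in js if j in stop_by_id
        )
        n_js = len(js)
        for k, tau in enumerate(r.clap_times, start=1):
            key = (tau, r.individual_id)
            n_stopped = bisect.bisect_left(stops_sorted, key)
            # the focal's own stop shares the key, so bisect_left excludes it
            rho_stopped = n_stopped / n
            nb = bisect.bisect_left(nbr_stops, key) / n_js if n_js else 0.0
            obs = StopObservation(
                individual_id=r.individual_id,
                time=tau,
                n_claps=k,
                rho_stopped=rho_stopped,
                neighbour_fraction=nb,
                outcome="stopped" if k == len(r.clap_times) else "continued",
            )
            if restrict_after_first_stop and rho_stopped <= 0.0:
                continue
            out.append(obs)
    return out
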
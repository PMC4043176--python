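"""Study-shaped synthetic data with known ground truth.

Emulates the experimental design behind the applause data — six groups
of sizes 20, 20, 20, 18, 16 and 13, seated in three rows, each attending
two talks, with 3 of the 107 participants never clapping and a ~2.1 s
latency from the end of the talk to the first clap — under *any*
candidate starting and stopping model, including neighbour-driven and
Gaussian variants.  This is the validation workhorse: generate under a
known model, re-fit, and check that parameters and model identity are
recovered.

Starting uses a competing-exponentials event loop over per-individual
hazards from :mod:`applause.starting_models` (hazards are constant
between start events, so the race is exact); stopping is the clap-by-
clap loop of the simulator but with the full stopping-model surface,
including neighbour cues evaluated on the seating grid.

Individual consistency — the tendency of the same people to clap early
in both talks — is injected by reassigning each bout's timing bundles to
individuals with a Plackett–Luce draw whose weights share a per-
individual latent "eagerness" across the group's two talks.  A
Plackett–Luce order is exactly the arrival order of an exponential race
with proportional hazards, so this is a multiplicative start-hazard
frailty that leaves every group-level curve unchanged; at effect 0 the
orders are independent (models stay well specified), at effect 1 the two
talks' orders are identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
from scipy.stats import spearmanr

from .event_data import Bout, ClapRecord
from .starting_models import (
    GAUSSIAN_START,
    GaussianStartParams,
    StartParams,
    parse_start_model,
    rate_from_fractions,
)
from .stopping_models import (
    GAUSSIAN_STOP,
    GaussianStopParams,
    StopParams,
    gaussian_stop_probability,
    parse_stop_model,
    prob_from_fractions,
)

__all__ = [
    "StudyDesign",
    "generate_study",
    "inject_individual_consistency",
    "calibrate_consistency_effect",
]


@dataclass(frozen=True)
class StudyDesign:
    """Shape of one synthetic study (defaults: the observed design)."""

    group_sizes: tuple[int, ...] = (20, 20, 20, 18, 16, 13)
    talks_per_group: int = 2
    n_rows: int = 3
    n_non_starters: int = 3
    latency_mean: float = 2.1  # seconds, truncated Normal >= 0
    latency_sd: float = 0.6

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.group_sizes):
            raise ValueError("group sizes must be positive")
        if self.n_non_starters >= min(self.group_sizes):
            raise ValueError("too many non-starters for the smallest group")

    def seats(self, size: int) -> list[tuple[int, int]]:
        """Distribute ``size`` seats as evenly as possible over the rows."""
        base, rem = divmod(size, self.n_rows)
        out = []
        for row in range(self.n_rows):
            for col in range(base + (1 if row < rem else 0)):
                out.append((row, col))
        return out


def _neighbour_indices(seats: Sequence[tuple[int, int]], include_diagonals: bool) -> list[list[int]]:
    by_seat = {seat: i for i, seat in enumerate(seats)}
    offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if include_diagonals:
        offsets += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    return [
        [by_seat[(r + dr, c + dc)] for dr, dc in offsets if (r + dr, c + dc) in by_seat]
        for r, c in seats
    ]


def _draw_interval(rng: np.random.Generator, mean: float, sd: float, cutoff: float) -> float:
    while True:
        t = rng.normal(mean, sd)
        if t >= cutoff:
            return t


def _generate_starts(
    n: int,
    participants: np.ndarray,
    neighbours: list[list[int]],
    start_model: str,
    start_params,
    rng: np.random.Generator,
) -> np.ndarray:
    """Start times (NaN for non-starters), origin at the first clap."""
    starts = np.full(n, np.nan)
    if start_model == GAUSSIAN_START:
        r = rng.normal(start_params.mu, start_params.sigma, size=len(participants))
        starts[participants] = r - r.min()
        return starts
    mask = parse_start_model(start_model)
    if set(start_params.mask) - set(mask):
        raise ValueError(f"params active {start_params.mask} not within model {mask}")
    started = np.zeros(n, dtype=bool)
    initiator = rng.choice(participants)
    started[initiator] = True
    starts[initiator] = 0.0
    t = 0.0
    remaining = [i for i in participants if i != initiator]
    while remaining:
        rho = started.sum() / n
        hazards = np.array(
            [
                rate_from_fractions(
                    rho,
                    (np.mean(started[neighbours[i]]) if neighbours[i] else 0.0),
                    start_params,
                )
                for i in remaining
            ]
        )
        total = hazards.sum()
        if total <= 0:
            raise RuntimeError(
                "starting stalled: every remaining susceptible has zero hazard "
                f"under model {start_model}"
            )
        t += rng.exponential(1.0 / total)
        j = rng.choice(len(remaining), p=hazards / total)
        i = remaining.pop(j)
        started[i] = True
        starts[i] = t
    return starts


def _generate_stops(
    starts: np.ndarray,
    n: int,
    neighbours: list[list[int]],
    stop_model: str,
    stop_params,
    rng: np.random.Generator,
    interval_mean: float,
    interval_sd: float,
    min_interval: float,
) -> list[list[float]]:
    import heapq

    if stop_model == GAUSSIAN_STOP:
        pass  # always terminates: the Normal hazard reaches 1 in the tail
    else:
        mask = parse_stop_model(stop_model)
        if set(stop_params.mask) - set(mask):
            raise ValueError(f"params active {stop_params.mask} not within model {mask}")
        if stop_params.gamma1 == 0 and stop_params.gamma3 == 0:
            raise ValueError(
                f"stop model {stop_model} with gamma1 = gamma3 = 0 can never "
                "initiate stopping; generation would not terminate"
            )
    heap = [(float(t), i) for i, t in enumerate(starts) if not math.isnan(t)]
    heapq.heapify(heap)
    claps: dict[int, list[float]] = {i: [] for _, i in heap}
    stopped = np.zeros(n, dtype=bool)
    n_stopped = 0
    while heap:
        t, i = heapq.heappop(heap)
        claps[i].append(t)
        k = len(claps[i])
        if stop_model == GAUSSIAN_STOP:
            p = gaussian_stop_probability(k, stop_params.m, stop_params.s)
        else:
            f_nbr = float(np.mean(stopped[neighbours[i]])) if neighbours[i] else 0.0
            p = prob_from_fractions(n_stopped / n, f_nbr, k, stop_params)
        if rng.random() < p:
            stopped[i] = True
            n_stopped += 1
        else:
            heapq.heappush(
                heap, (t + _draw_interval(rng, interval_mean, interval_sd, min_interval), i)
            )
    return claps


def generate_study(
    design: StudyDesign,
    start_model: str,
    start_params: StartParams | GaussianStartParams,
    stop_model: str,
    stop_params: StopParams | GaussianStopParams,
    seed: int | None = None,
    interval_mean: float = 0.28,
    interval_sd: float = 0.09,
    min_interval: float = 0.01,
    include_diagonals: bool = False,
) -> list[Bout]:
    """Generate a full study (all groups × talks) under the given models.

    Non-starters are drawn once per study from the pooled audience and
    never clap in either talk; they keep their seats, so neighbour
    fractions see them.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    # designate study-wide non-starters among pooled (group, index) pairs
    pool = [(g, i) for g, size in enumerate(design.group_sizes) for i in range(size)]
    non_idx = rng.choice(len(pool), size=design.n_non_starters, replace=False)
    non_starters = {pool[int(j)] for j in non_idx}
    bouts = []
    for g, size in enumerate(design.group_sizes):
        seats = design.seats(size)
        neighbours = _neighbour_indices(seats, include_diagonals)
        participants = np.array(
            [i for i in range(size) if (g, i) not in non_starters], dtype=int
        )
        gid = f"g{g + 1}"
        for talk in range(1, design.talks_per_group + 1):
            starts = _generate_starts(
                size, participants, neighbours, start_model, start_params, rng
            )
            claps = _generate_stops(
                starts, size, neighbours, stop_model, stop_params, rng,
                interval_mean, interval_sd, min_interval,
            )
            latency = max(0.0, rng.normal(design.latency_mean, design.latency_sd))
            records = []
            for i in range(size):
                row, col = seats[i]
                if math.isnan(starts[i]):
                    records.append(
                        ClapRecord(gid, talk, f"{gid}-{i:02d}", row, col, None)
                    )
                else:
                    ct = tuple(claps[i])
                    records.append(
                        ClapRecord(
                            gid, talk, f"{gid}-{i:02d}", row, col,
                            start_time=ct[0], stop_time=ct[-1],
                            clap_times=ct, n_claps=len(ct),
                        )
                    )
            bouts.append(Bout(tuple(records), latency=latency))
    return bouts


# ---------------------------------------------------------------------------
# Individual consistency


def _pl_order(eta: np.ndarray, rng: np.random.Generator, deterministic: bool) -> np.ndarray:
    """Plackett–Luce order with weights exp(eta) via the Gumbel trick."""
    if deterministic:
        return np.argsort(-eta, kind="stable")
    gumbel = -np.log(-np.log(rng.random(len(eta))))
    return np.argsort(-(eta + gumbel), kind="stable")


def inject_individual_consistency(
    bouts: Sequence[Bout], effect: float, seed: int | None = None
) -> list[Bout]:
    """Correlate start orders across each group's two talks.

    ``effect`` in [0, 1] scales a per-individual latent eagerness shared
    across talks: 0 leaves orders independent, 1 makes them identical.
    Within each bout the starters' timing bundles (start, claps, stop)
    are re-dealt to individuals in a Plackett–Luce order on
    exp(τ·(√e·z_i + √(1−e)·ε)), τ = 2/(1−e) — the proportional-hazards
    frailty race — so every group-level statistic is untouched.
    """
    if not 0.0 <= effect <= 1.0:
        raise ValueError("effect must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    by_group: dict[str, list[Bout]] = {}
    for bout in bouts:
        by_group.setdefault(bout.group_id, []).append(bout)
    out = []
    for gid in sorted(by_group):
        talks = sorted(by_group[gid], key=lambda b: b.talk_id)
        if len(talks) < 2:
            raise ValueError(f"group {gid} has fewer than two talks")
        ids = sorted(r.individual_id for r in talks[0].records)
        z = {iid: rng.normal() for iid in ids}
        for bout in talks:
            starters = sorted(bout.starters, key=lambda r: (r.start_time, r.individual_id))
            starter_ids = [r.individual_id for r in starters]
            zvec = np.array([z[iid] for iid in starter_ids])
            if effect == 1.0:
                eta, det = zvec, True
            else:
                tau = 2.0 / (1.0 - effect)
                eta = tau * (
                    math.sqrt(effect) * zvec
                    + math.sqrt(1.0 - effect) * rng.normal(size=len(zvec))
                )
                det = False
            order = _pl_order(eta, rng, det)
            bundles = [(r.start_time, r.stop_time, r.clap_times, r.n_claps) for r in starters]
            new_records = {r.individual_id: r for r in bout.records if not r.is_starter}
            for rank, idx in enumerate(order):
                iid = starter_ids[idx]
                start, stop, ct, nc = bundles[rank]
                old = bout.record_of(iid)
                new_records[iid] = replace(
                    old, start_time=start, stop_time=stop, clap_times=ct, n_claps=nc
                )
            out.append(
                Bout(
                    tuple(new_records[r.individual_id] for r in bout.records),
                    latency=bout.latency,
                )
            )
    return out


def calibrate_consistency_effect(
    target_rho: float,
    study_factory: Callable[[int], Sequence[Bout]],
    n_studies: int = 30,
    seed: int = 0,
    iterations: int = 10,
) -> float:
    """Find the effect size whose median cross-talk Spearman ρ hits a target.

    Bisection with common random numbers: each candidate effect is scored
    on the same ``n_studies`` freshly generated studies, measuring the
    pooled median Spearman correlation of start orders between talks.
    """

    def median_rho(effect: float) -> float:
        rhos = []
        for rep in range(n_studies):
            bouts = inject_individual_consistency(
                study_factory(seed + 1000 + rep), effect, seed=seed + 2000 + rep
            )
            by_group: dict[str, list[Bout]] = {}
            for b in bouts:
                by_group.setdefault(b.group_id, []).append(b)
            for talks in by_group.values():
                talks = sorted(talks, key=lambda b: b.talk_id)
                shared = sorted(
                    {r.individual_id for r in talks[0].starters}
                    & {r.individual_id for r in talks[1].starters}
                )
                if len(shared) < 3:
                    continue
                s1 = [talks[0].record_of(i).start_time for i in shared]
                s2 = [talks[1].record_of(i).start_time for i in shared]
                rhos.append(spearmanr(s1, s2).statistic)
        return float(np.median(rhos))

    lo, hi = 0.0, 1.0
    for _ in range(iterations):
        mid = (lo + hi) / 2
        if median_rho(mid) < target_rho:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2
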
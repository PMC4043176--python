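"""Stochastic applause-bout simulator.

The audience of N individuals passes through susceptible (S), clapping
(I) and recovered (R) states.  Starting: the first individual claps at
t=0; while susceptibles remain, each has hazard λ2·(I+R) of starting (I,
R as proportions of N), so the waiting time to the next start is
exponential with total rate λ2·(number susceptible)·(I+R).  Stopping:
claps are processed event by event in time order; after its n-th clap an
individual stops with probability γ1 + γ2·R + γ3·n/n_max (clamped), or
claps again after a Normal(0.28 s, 0.09 s) interval (truncated away from
zero).  The bout ends when everyone has stopped.

The literal proportion-product reading of the start stage (total rate
λ2·S·(I+R) with S a proportion) is available via
``literal_proportion_rates=True``; it stretches a 20-person audience's
start spread by a factor of N and is kept only for comparison.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .event_data import Bout, ClapRecord
from .stopping_models import StopParams, prob_from_fractions

__all__ = [
    "SimConfig",
    "simulate_starts",
    "simulate_stops",
    "simulate_bout",
    "run_ensemble",
    "sample_start_spreads",
    "expected_start_spread",
]


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters; defaults are the best-fit applause model."""

    n_individuals: int = 20
    lambda2: float = 2.15  # per second
    stop_params: StopParams = field(
        default_factory=lambda: StopParams(gamma2=0.63, gamma3=0.05, n_max=30)
    )
    interval_mean: float = 0.28  # seconds between claps
    interval_sd: float = 0.09
    min_interval: float = 0.01  # redraw threshold for the truncated Normal
    n_runs: int = 1
    seed: int | None = None
    literal_proportion_rates: bool = False

    def __post_init__(self) -> None:
        if self.n_individuals < 2:
            raise ValueError("need at least 2 individuals")
        if self.lambda2 < 0 or self.interval_mean <= 0 or self.interval_sd < 0:
            raise ValueError("invalid rate or interval parameters")
        if self.stop_params.gamma4 > 0:
            raise ValueError(
                "the global simulator has no seating; neighbour-driven stopping "
                "belongs to synthetic_data.generate_study"
            )


def simulate_starts(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Ordered start times t(1..N) with t(1) = 0.

    After k individuals have started, the waiting time to the next start
    is exponential with rate λ2·(N−k)·(k/N) — each of the N−k remaining
    susceptibles carries hazard λ2·(I+R) = λ2·k/N.
    """
    if config.lambda2 == 0:
        raise ValueError("lambda2 = 0: clapping can never spread beyond the initiator")
    n = config.n_individuals
    t = 0.0
    times = [0.0]
    for k in range(1, n):
        rate = config.lambda2 * (k / n) * ((n - k) if not config.literal_proportion_rates else (n - k) / n)
        t += rng.exponential(1.0 / rate)
        times.append(t)
    return np.asarray(times)


class _IntervalSampler:
    """Buffered truncated-Normal clap-interval sampler (redraw below cutoff)."""

    def __init__(self, rng: np.random.Generator, mean: float, sd: float, cutoff: float):
        self.rng, self.mean, self.sd, self.cutoff = rng, mean, sd, cutoff
        self.buf: list[float] = []

    def __call__(self) -> float:
        while not self.buf:
            draws = self.rng.normal(self.mean, self.sd, size=256)
            self.buf = draws[draws >= self.cutoff].tolist()
        return self.buf.pop()


def simulate_stops(
    start_times: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
    group_id: str = "sim",
    talk_id: int = 1,
) -> list[ClapRecord]:
    """Clap-by-clap stopping stage: returns one record per individual.

    Each individual's first clap is at their start time.  Claps are
    processed in time order (ties by index); after clap n the individual
    stops with the per-clap probability from the stop parameters, with
    the stopped fraction updated at the instant of each stop.
    """
    p = config.stop_params
    if p.gamma1 == 0 and p.gamma3 == 0:
        raise ValueError(
            "gamma1 = gamma3 = 0: no individual can ever initiate stopping, "
            "the simulation would not terminate"
        )
    n = len(start_times)
    draw_interval = _IntervalSampler(
        rng, config.interval_mean, config.interval_sd, config.min_interval
    )
    heap = [(float(t), i) for i, t in enumerate(start_times)]
    heapq.heapify(heap)
    claps: list[list[float]] = [[] for _ in range(n)]
    n_claps = [0] * n
    n_stopped = 0
    while heap:
        t, i = heapq.heappop(heap)
        n_claps[i] += 1
        claps[i].append(t)
        p_stop = prob_from_fractions(n_stopped / n, 0.0, n_claps[i], p)
        if rng.random() < p_stop:
            n_stopped += 1
        else:
            heapq.heappush(heap, (t + draw_interval(), i))
    ncols = max(1, math.ceil(n / 3))
    return [
        ClapRecord(
            group_id=group_id,
            talk_id=talk_id,
            individual_id=f"{group_id}-{i:03d}",
            seat_row=i // ncols,
            seat_col=i % ncols,
            start_time=claps[i][0],
            stop_time=claps[i][-1],
            clap_times=tuple(claps[i]),
            n_claps=len(claps[i]),
        )
        for i in range(n)
    ]


def simulate_bout(
    config: SimConfig, rng: np.random.Generator, group_id: str = "sim", talk_id: int = 1
) -> Bout:
    starts = simulate_starts(config, rng)
    return Bout(tuple(simulate_stops(starts, config, rng, group_id, talk_id)))


def _summarize(bout: Bout) -> dict[str, float]:
    starts = np.array([r.start_time for r in bout.starters])
    stops = np.array([r.stop_time for r in bout.starters])
    claps = np.array([len(r.clap_times) for r in bout.starters])
    return {
        "duration": float(stops.max() - starts.min()),
        "start_spread": float(starts.max() - starts.min()),
        "stop_spread": float(stops.max() - stops.min()),
        "first_stop": float(stops.min()),
        "mean_claps": float(claps.mean()),
    }


def run_ensemble(config: SimConfig) -> tuple[list[Bout], pd.DataFrame]:
    """Simulate ``config.n_runs`` bouts; per-run summary statistics.

    Summaries follow the observational definitions: bout duration (first
    start to last stop), start spread (first to last start), stop spread
    (first to last stop) and mean claps per starter.  Reproducible given
    ``config.seed``.
    """
    if config.n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    ss = np.random.SeedSequence(config.seed)
    bouts, rows = [], []
    for run, child in enumerate(ss.spawn(config.n_runs)):
        rng = np.random.default_rng(child)
        bout = simulate_bout(config, rng, group_id=f"run{run:05d}")
        bouts.append(bout)
        rows.append({"run": run, **_summarize(bout)})
    return bouts, pd.DataFrame(rows)


def sample_start_spreads(
    lambda2: float, n_individuals: int, n_samples: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorised draws of the first-to-last-start interval.

    Equivalent in distribution to ``simulate_starts`` (a sum of N−1
    independent exponential stages); used for large ensembles.
    """
    if lambda2 <= 0:
        raise ValueError("lambda2 must be positive")
    n = n_individuals
    k = np.arange(1, n)
    scales = 1.0 / (lambda2 * (n - k) * (k / n))
    return rng.exponential(scales, size=(n_samples, n - 1)).sum(axis=1)


def expected_start_spread(lambda2: float, n_individuals: int) -> float:
    """Closed-form mean start spread, (2/λ2)·H_{N−1}.

    Stage k has rate λ2·(N−k)·k/N; summing 1/rate over k = 1..N−1 and
    splitting 1/((N−k)k) into partial fractions gives (2/λ2)·H_{N−1}.
    """
    h = np.sum(1.0 / np.arange(1, n_individuals))
    return 2.0 * h / lambda2
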
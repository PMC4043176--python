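"""Study-level summaries and statistics for applause bouts.

Works identically on observed-schema and simulated bouts (one shared
code path): per-bout interval statistics, median ± interquartile S/I/R
curves, the claps-per-person distribution with a matched-Poisson overlay
and central-95% coverage check, and the cross-talk individual-consistency
test (Spearman rank correlation with a within-group randomisation
p-value).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .event_data import Bout, fractions_on_grid

__all__ = [
    "BoutSummary",
    "summarize_bouts",
    "sir_curves",
    "claps_distribution",
    "consistency_test",
]


@dataclass(frozen=True)
class BoutSummary:
    """Interval statistics of one bout (seconds; claps for mean_claps)."""

    group_id: str
    talk_id: int
    first_start_latency: float | None
    start_spread: float
    stop_spread: float
    bout_length: float
    mean_claps: float | None
    first_stop: float
    single_starter: bool

    def __post_init__(self) -> None:
        if min(self.start_spread, self.stop_spread, self.bout_length) < 0:
            raise ValueError("interval statistics must be non-negative")
        if self.bout_length < max(self.start_spread, self.stop_spread) - 1e-9:
            raise ValueError("bout length cannot be below either spread")


def summarize_bouts(bouts: Sequence[Bout]) -> tuple[list[BoutSummary], pd.DataFrame]:
    """Per-bout summaries plus across-bout means with standard errors.

    Bout length runs from the first start to the last stop; spreads from
    first to last start and first to last stop.  Standard errors are
    sample sd / sqrt(number of bouts).  A bout with a single starter gets
    zero spreads and is flagged.
    """
    if not bouts:
        raise ValueError("need at least one bout")
    summaries = []
    for bout in bouts:
        starts = np.array([r.start_time for r in bout.starters])
        stops = np.array([r.stop_time for r in bout.starters])
        with_claps = [r for r in bout.starters if r.clap_times is not None]
        mean_claps = (
            float(np.mean([len(r.clap_times) for r in with_claps])) if with_claps else None
        )
        summaries.append(
            BoutSummary(
                group_id=bout.group_id,
                talk_id=bout.talk_id,
                first_start_latency=bout.latency,
                start_spread=float(starts.max() - starts.min()),
                stop_spread=float(stops.max() - stops.min()),
                bout_length=float(stops.max() - starts.min()),
                mean_claps=mean_claps,
                first_stop=float(stops.min()),
                single_starter=len(starts) == 1,
            )
        )
    cols = ["start_spread", "stop_spread", "bout_length", "mean_claps", "first_stop",
            "first_start_latency"]
    table = pd.DataFrame([{c: getattr(s, c) for c in cols} for s in summaries])
    agg = pd.DataFrame(
        {
            "mean": table.mean(),
            "se": table.std(ddof=1) / math.sqrt(len(table)) if len(table) > 1 else 0.0,
            "n": table.count(),
        }
    )
    return summaries, agg


def sir_curves(
    bouts: Sequence[Bout], time_grid: np.ndarray | None = None
) -> pd.DataFrame:
    """Median and interquartile bands of the started / stopped / currently
    clapping fractions across bouts, on absolute time from the first clap."""
    if len(bouts) < 2:
        raise ValueError("need at least two bouts for quartile bands")
    if time_grid is None:
        horizon = max(b.end_time for b in bouts)
        time_grid = np.linspace(0.0, horizon, 200)
    time_grid = np.asarray(time_grid, float)
    started = np.empty((len(bouts), len(time_grid)))
    stopped = np.empty_like(started)
    for i, bout in enumerate(bouts):
        started[i], stopped[i] = fractions_on_grid(bout, time_grid)
    current = started - stopped
    out = {"t": time_grid}
    for name, arr in [("started", started), ("stopped", stopped), ("current", current)]:
        out[f"{name}_median"] = np.median(arr, axis=0)
        out[f"{name}_q25"] = np.quantile(arr, 0.25, axis=0)
        out[f"{name}_q75"] = np.quantile(arr, 0.75, axis=0)
    return pd.DataFrame(out)


def claps_distribution(
    mean_claps: Sequence[float] | pd.Series,
    observed: Sequence[float] | None = None,
) -> dict:
    """Distribution of per-run mean claps/person with a Poisson overlay.

    Histogram on unit bins; the dashed-line comparison is the Poisson pmf
    matched to the ensemble mean.  ``variance_ratio`` > 1 quantifies the
    over-dispersion of the simulated distribution relative to Poisson.
    Each ``observed`` bout mean is checked against the central 95% of the
    ensemble (2.5–97.5 percentiles).
    """
    values = np.asarray(mean_claps, float)
    if len(values) < 100:
        raise ValueError("need an ensemble of at least 100 runs")
    mean = float(values.mean())
    var = float(values.var(ddof=1))
    edges = np.arange(math.floor(values.min()), math.ceil(values.max()) + 1.0)
    if len(edges) < 2:
        edges = np.array([edges[0], edges[0] + 1.0])
    hist, _ = np.histogram(values, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2
    poisson_pmf = stats.poisson(mean).pmf(np.round(centers).astype(int))
    lo, hi = np.quantile(values, [0.025, 0.975])
    result = {
        "bin_edges": edges,
        "proportions": hist / len(values),
        "bin_centers": centers,
        "poisson_pmf": poisson_pmf,
        "mean": mean,
        "variance": var,
        "variance_ratio": var / mean if mean > 0 else math.nan,
        "central95": (float(lo), float(hi)),
    }
    if observed is not None:
        obs = np.asarray(observed, float)
        result["observed"] = obs
        result["observed_in_central95"] = (obs >= lo) & (obs <= hi)
    return result


def _order_ranks(bout: Bout, shared: Sequence[str], what: str) -> np.ndarray:
    times = [
        getattr(bout.record_of(i), "start_time" if what == "start" else "stop_time")
        for i in shared
    ]
    return stats.rankdata(times)


def consistency_test(
    bouts: Sequence[Bout],
    n_randomizations: int = 10_000,
    seed: int | None = None,
) -> dict:
    """Cross-talk consistency of individual start (and stop) orders.

    For each group with two talks and >= 3 shared starters, the Spearman
    correlation between the two talks' start-order ranks (and stop-order
    ranks).  The test statistic is the pooled median ρ across groups; the
    null distribution permutes one talk's order independently within each
    group.  p is the fraction of null medians at least as large as the
    observed one (add-one correction).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    by_group: dict[str, list[Bout]] = {}
    for bout in bouts:
        by_group.setdefault(bout.group_id, []).append(bout)
    group_rows = []
    rank_pairs: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    excluded = []
    for gid in sorted(by_group):
        talks = sorted(by_group[gid], key=lambda b: b.talk_id)
        if len(talks) != 2:
            raise ValueError(f"group {gid} must have exactly two talks")
        shared = sorted(
            {r.individual_id for r in talks[0].starters}
            & {r.individual_id for r in talks[1].starters}
        )
        if len(shared) < 3:
            excluded.append(gid)
            continue
        pairs = {}
        row = {"group_id": gid, "n_shared": len(shared)}
        for what in ("start", "stop"):
            r1 = _order_ranks(talks[0], shared, what)
            r2 = _order_ranks(talks[1], shared, what)
            pairs[what] = (r1, r2)
            row[f"rho_{what}"] = float(stats.spearmanr(r1, r2).statistic)
        rank_pairs[gid] = pairs
        group_rows.append(row)
    if not group_rows:
        raise ValueError("no group with at least 3 shared starters")
    per_group = pd.DataFrame(group_rows)
    result = {"per_group": per_group, "excluded_groups": excluded,
              "n_randomizations": n_randomizations}
    for what in ("start", "stop"):
        observed = float(per_group[f"rho_{what}"].median())
        null_rhos = np.empty((len(rank_pairs), n_randomizations))
        for g, pairs in enumerate(rank_pairs.values()):
            r1, r2 = pairs[what]
            c1 = r1 - r1.mean()
            perms = np.argsort(rng.random((n_randomizations, len(r2))), axis=1)
            shuffled = r2[perms]
            c2 = shuffled - shuffled.mean(axis=1, keepdims=True)
            denom = np.sqrt((c1**2).sum() * (c2**2).sum(axis=1))
            null_rhos[g] = (c2 @ c1) / denom
        null_medians = np.median(null_rhos, axis=0)
        p = (1.0 + np.sum(null_medians >= observed - 1e-12)) / (1.0 + n_randomizations)
        result[f"median_rho_{what}"] = observed
        result[f"p_{what}"] = float(p)
    return result
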
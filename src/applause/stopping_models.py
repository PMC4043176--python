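"""Per-clap stopping models and their log-likelihoods.

After each clap an individual stops with probability

    P_stop = γ1 + γ2·ρ_stopped + γ3·n_claps/n_max + γ4·f_neighbours_stopped

clamped to [0, 1]: a constant urge to stop (G1), a social response to the
fraction of the audience that has already stopped (G2), an increasing
reluctance to keep clapping, normalised by the maximum clap count n_max
(G3), and a response to stopped seat neighbours (G4).  Alternatively,
individuals clap a normally distributed number of times, independent of
the group ("G_stop"); its per-clap hazard uses a half-integer continuity
correction on the discrete clap count.

A model containing only social terms (subsets of {G2, G4}) assigns zero
probability to the bout's first stop, so its likelihood on unrestricted
data is −inf — the structural impossibility of a purely social account
of *initiating* stopping.  On data restricted to claps after the first
stop, the purely social model is well defined.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import log_ndtr

from .event_data import AudienceState, Bout, StopObservation, make_stop_observations
from .starting_models import _log_normal_interval

__all__ = [
    "StopParams",
    "GaussianStopParams",
    "stop_probability",
    "prob_from_fractions",
    "gaussian_stop_probability",
    "stop_loglik",
    "parse_stop_model",
    "format_stop_model",
    "PackedStopData",
    "stop_rate_loglik_batch",
    "gaussian_stop_loglik_batch",
]

log = logging.getLogger(__name__)

GAUSSIAN_STOP = "G_stop"
DEFAULT_N_MAX = 30  # simulation default; bouts can run past 30 claps


def parse_stop_model(name: str) -> tuple[int, ...]:
    """``"G2+G3"`` → ``(2, 3)``; ``"G_stop"`` is handled separately."""
    mask = []
    for term in name.split("+"):
        if not (len(term) == 2 and term[0] == "G" and term[1] in "1234"):
            raise ValueError(f"unknown stopping-model term {term!r}")
        mask.append(int(term[1]))
    if len(set(mask)) != len(mask) or not mask:
        raise ValueError(f"invalid stopping model {name!r}")
    return tuple(sorted(mask))


def format_stop_model(mask: Iterable[int]) -> str:
    return "+".join(f"G{i}" for i in sorted(mask))


@dataclass(frozen=True)
class StopParams:
    """Per-clap stopping probabilities for the four combinable terms."""

    gamma1: float = 0.0
    gamma2: float = 0.0
    gamma3: float = 0.0
    gamma4: float = 0.0
    n_max: int = DEFAULT_N_MAX
    mask: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        g = self.as_array()
        if np.any(g < 0):
            raise ValueError(f"negative stopping parameter in {g}")
        if self.n_max <= 0:
            raise ValueError("n_max must be positive")
        if self.mask is None:
            object.__setattr__(self, "mask", tuple(i + 1 for i in range(4) if g[i] > 0))
        else:
            object.__setattr__(self, "mask", tuple(sorted(self.mask)))
            inactive = [i + 1 for i in range(4) if (i + 1) not in self.mask and g[i] != 0]
            if inactive:
                raise ValueError(f"inactive terms {inactive} must be exactly 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.gamma1, self.gamma2, self.gamma3, self.gamma4], dtype=float)

    @classmethod
    def from_mask(
        cls, mask: Sequence[int], values: Sequence[float], n_max: int = DEFAULT_N_MAX
    ) -> "StopParams":
        g = [0.0] * 4
        for i, v in zip(mask, values):
            g[i - 1] = float(v)
        return cls(*g, n_max=n_max, mask=tuple(sorted(mask)))


@dataclass(frozen=True)
class GaussianStopParams:
    """Preferred-duration model: clap count ~ Normal(m, s), in claps."""

    m: float
    s: float

    def __post_init__(self) -> None:
        if self.m <= 0 or self.s <= 0:
            raise ValueError("m and s must be positive")


def prob_from_fractions(
    rho_stopped: float, neighbour_fraction: float, n_claps: int, params: StopParams
) -> float:
    """Per-clap stopping probability given the audience fractions, clamped."""
    if n_claps < 1:
        raise ValueError("n_claps must be >= 1")
    p = (
        params.gamma1
        + params.gamma2 * rho_stopped
        + params.gamma3 * n_claps / params.n_max
        + params.gamma4 * neighbour_fraction
    )
    return min(max(p, 0.0), 1.0)


def stop_probability(state: AudienceState, focal_id: str, n_claps: int, params: StopParams) -> float:
    """Stopping probability of a clapping focal individual after clap n."""
    if state.phase.get(focal_id) != "I":
        raise ValueError(f"{focal_id} is not clapping at t={state.time}")
    return prob_from_fractions(
        state.rho_stopped, state.neighbour_stopped.get(focal_id, 0.0), n_claps, params
    )


def gaussian_stop_probability(n_claps: int, m: float, s: float) -> float:
    """Discrete hazard of stopping at clap n for a Normal(m, s) clap count.

    (Φ(n+½) − Φ(n−½)) / (1 − Φ(n−½)), clamped to [0, 1]; survivor
    underflow forces probability 1 (logged).
    """
    if n_claps < 1:
        raise ValueError("n_claps must be >= 1")
    a, b = (n_claps - 0.5 - m) / s, (n_claps + 0.5 - m) / s
    log_sf = log_ndtr(-a)
    if not np.isfinite(log_sf) or log_sf < -700:
        log.warning("clap-count survivor underflow at n=%d (m=%.2f, s=%.2f)", n_claps, m, s)
        return 1.0
    p = math.exp(float(_log_normal_interval(a, b)) - float(log_sf))
    return min(max(p, 0.0), 1.0)


def stop_loglik(
    observations: Sequence[StopObservation],
    model: str,
    params: StopParams | GaussianStopParams,
) -> float:
    """Log-likelihood of per-clap stopping observations under one model.

    Returns −inf with a diagnostic if an observed stop has probability 0
    (e.g. a purely social model facing the bout's first stop) or an
    observed continuation has probability 1.
    """
    total = 0.0
    for obs in observations:
        if model == GAUSSIAN_STOP:
            p = gaussian_stop_probability(obs.n_claps, params.m, params.s)
        else:
            mask = parse_stop_model(model)
            if set(params.mask) - set(mask):
                raise ValueError(f"params active {params.mask} not within model {mask}")
            p = prob_from_fractions(
                obs.rho_stopped, obs.neighbour_fraction, obs.n_claps, params
            )
        if obs.stopped:
            if p <= 0.0:
                log.warning(
                    "observed stop with zero probability (%s, clap %d): "
                    "model %s cannot explain the data",
                    obs.individual_id,
                    obs.n_claps,
                    model,
                )
                return -math.inf
            total += math.log(p)
        else:
            if p >= 1.0:
                return -math.inf
            total += math.log1p(-p)
    return total


# ---------------------------------------------------------------------------
# Packed arrays


@dataclass(frozen=True)
class PackedStopData:
    """Stopping observations packed for vectorised likelihoods.

    ``x`` holds feature rows [1, ρ_stopped, n/n_max, f_nbr] for every
    clap; ``stopped`` flags the final clap of each individual.  For the
    Gaussian model only the clap index matters, so per-count tallies of
    stops and continuations suffice.
    """

    x: np.ndarray  # (n_obs, 4)
    stopped: np.ndarray  # (n_obs,) bool
    n_claps: np.ndarray  # (n_obs,) int
    n_max: int

    @classmethod
    def from_observations(
        cls, observations: Sequence[StopObservation], n_max: int | None = None
    ) -> "PackedStopData":
        n_arr = np.array([o.n_claps for o in observations], dtype=int)
        if n_max is None:
            n_max = int(n_arr.max()) if len(n_arr) else DEFAULT_N_MAX
        if len(n_arr) and n_max < n_arr.max():
            # legitimate when fitting at the n_max a simulation was run with:
            # the per-clap hazard need not reach 1 at n_max
            log.warning(
                "n_max=%d below the maximum observed claps %d; the clap-count "
                "feature exceeds 1 for the longest bouts",
                n_max,
                n_arr.max(),
            )
        x = np.array(
            [
                (1.0, o.rho_stopped, o.n_claps / n_max, o.neighbour_fraction)
                for o in observations
            ],
            dtype=float,
        ).reshape(-1, 4)
        stopped = np.array([o.stopped for o in observations], dtype=bool)
        return cls(x=x, stopped=stopped, n_claps=n_arr, n_max=n_max)

    @classmethod
    def from_bouts(
        cls,
        bouts: Sequence[Bout],
        restrict_after_first_stop: bool = False,
        n_max: int | None = None,
        include_diagonals: bool = False,
    ) -> "PackedStopData":
        obs: list[StopObservation] = []
        for bout in bouts:
            obs.extend(
                make_stop_observations(bout, restrict_after_first_stop, include_diagonals)
            )
        return cls.from_observations(obs, n_max)


def stop_rate_loglik_batch(
    data: PackedStopData, gam: np.ndarray, chunk: int = 512
) -> np.ndarray:
    """Vectorised stop log-likelihood for many γ draws (shape (n_draws, 4))."""
    gam = np.atleast_2d(np.asarray(gam, float))
    out = np.empty(len(gam))
    xs, xc = data.x[data.stopped], data.x[~data.stopped]
    for lo in range(0, len(gam), chunk):
        g = gam[lo : lo + chunk]
        ps = np.clip(xs @ g.T, 0.0, 1.0)
        pc = np.clip(xc @ g.T, 0.0, 1.0)
        with np.errstate(divide="ignore"):
            ll = np.where(ps > 0, np.log(ps), -np.inf).sum(axis=0)
            ll += np.where(pc < 1, np.log1p(-pc), -np.inf).sum(axis=0)
        out[lo : lo + chunk] = ll
    return out


def gaussian_stop_loglik_batch(data: PackedStopData, theta: np.ndarray) -> np.ndarray:
    """Vectorised preferred-duration log-likelihood for (m, s) draws."""
    theta = np.atleast_2d(np.asarray(theta, float))
    if not len(data.n_claps):
        return np.zeros(len(theta))
    m, s = theta[:, 0], theta[:, 1]
    counts = np.arange(1, data.n_claps.max() + 1)
    tally_stop = np.bincount(data.n_claps[data.stopped], minlength=len(counts) + 1)[1:]
    tally_cont = np.bincount(data.n_claps[~data.stopped], minlength=len(counts) + 1)[1:]
    a = (counts[:, None] - 0.5 - m) / s  # (n_counts, n_draws)
    b = (counts[:, None] + 0.5 - m) / s
    log_sf = log_ndtr(-a)
    underflow = ~np.isfinite(log_sf) | (log_sf < -700)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_h = np.where(underflow, 0.0, np.minimum(_log_normal_interval(a, b) - log_sf, 0.0))
        log_1mh = np.where(underflow, -np.inf, np.log1p(-np.exp(log_h)))
    # guard 0 × (−inf) when a count has no observations of one outcome
    with np.errstate(invalid="ignore"):
        term_stop = np.where(tally_stop[:, None] > 0, tally_stop[:, None] * log_h, 0.0)
        term_cont = np.where(tally_cont[:, None] > 0, tally_cont[:, None] * log_1mh, 0.0)
    return term_stop.sum(axis=0) + term_cont.sum(axis=0)
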
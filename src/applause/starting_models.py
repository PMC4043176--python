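"""Hazard models for *starting* to clap and their log-likelihoods.

Four rate terms can be combined freely: a constant background rate (L1),
a rate proportional to the fraction of the audience already clapping
(L2), to the square of that fraction (L3, a threshold-like response) and
to the fraction of immediate seat neighbours clapping (L4).  The per-
second hazard of a susceptible individual is

    rate = λ1 + λ2·ρ_clapping + λ3·ρ_clapping² + λ4·f_neighbours

Alternatively, individuals may simply react to the first clap with a
normally distributed response time ("G_start"); the per-frame probability
is then the conditional Normal mass of the frame given survival to its
start.

Per-frame probabilities use p = 1 − exp(−rate·dt), so inference is stable
under refinement of the frame length.  The default log-likelihood uses
the event-history *density* convention: frames in which a start occurred
contribute log(p/dt).  This converges to the continuous-time likelihood
as dt → 0 and makes the total log-likelihood insensitive to the frame
length; set ``time_density=False`` for the raw product of frame
probabilities.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import log_ndtr

from .event_data import AudienceState, Bout, StartObservation, make_start_observations

__all__ = [
    "StartParams",
    "GaussianStartParams",
    "start_rate",
    "rate_from_fractions",
    "start_frame_probability",
    "gaussian_start_probability",
    "start_loglik",
    "parse_start_model",
    "format_start_model",
    "PackedStartData",
    "rate_loglik_batch",
    "gaussian_loglik_batch",
]

log = logging.getLogger(__name__)

GAUSSIAN_START = "G_start"


def parse_start_model(name: str) -> tuple[int, ...]:
    """``"L2+L4"`` → ``(2, 4)``.  ``"G_start"`` is handled separately."""
    terms = sorted(name.split("+"))
    mask = []
    for term in terms:
        if not (len(term) == 2 and term[0] == "L" and term[1] in "1234"):
            raise ValueError(f"unknown starting-model term {term!r}")
        mask.append(int(term[1]))
    if len(set(mask)) != len(mask) or not mask:
        raise ValueError(f"invalid starting model {name!r}")
    return tuple(sorted(mask))


def format_start_model(mask: Iterable[int]) -> str:
    return "+".join(f"L{i}" for i in sorted(mask))


@dataclass(frozen=True)
class StartParams:
    """Rates (per second) for the four combinable starting terms.

    Terms absent from ``mask`` must be exactly zero; ``mask`` defaults to
    the set of non-zero rates.
    """

    lam1: float = 0.0
    lam2: float = 0.0
    lam3: float = 0.0
    lam4: float = 0.0
    mask: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        lams = self.as_array()
        if np.any(lams < 0):
            raise ValueError(f"negative starting rate in {lams}")
        if self.mask is None:
            object.__setattr__(self, "mask", tuple(i + 1 for i in range(4) if lams[i] > 0))
        else:
            object.__setattr__(self, "mask", tuple(sorted(self.mask)))
            inactive = [i + 1 for i in range(4) if (i + 1) not in self.mask and lams[i] != 0]
            if inactive:
                raise ValueError(f"inactive terms {inactive} must be exactly 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.lam1, self.lam2, self.lam3, self.lam4], dtype=float)

    @classmethod
    def from_mask(cls, mask: Sequence[int], values: Sequence[float]) -> "StartParams":
        lams = [0.0] * 4
        for i, v in zip(mask, values):
            lams[i - 1] = float(v)
        return cls(*lams, mask=tuple(sorted(mask)))


@dataclass(frozen=True)
class GaussianStartParams:
    """First-clap reaction model: response time ~ Normal(mu, sigma), seconds."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.sigma <= 0:
            raise ValueError("mu and sigma must be positive")


def rate_from_fractions(
    rho_clapping: float, neighbour_fraction: float, params: StartParams
) -> float:
    """Starting hazard (per second) given the audience fractions."""
    return (
        params.lam1
        + params.lam2 * rho_clapping
        + params.lam3 * rho_clapping**2
        + params.lam4 * neighbour_fraction
    )


def start_rate(state: AudienceState, focal_id: str, params: StartParams) -> float:
    """Starting hazard of a susceptible focal individual in ``state``."""
    if state.phase.get(focal_id) != "S":
        raise ValueError(f"{focal_id} is not susceptible at t={state.time}")
    return rate_from_fractions(
        state.rho_clapping, state.neighbour_clapping.get(focal_id, 0.0), params
    )


def start_frame_probability(rate: float, dt: float) -> float:
    """Probability of starting within a frame of length dt at constant hazard."""
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if dt <= 0:
        raise ValueError("dt must be positive")
    return -math.expm1(-rate * dt)


def _log_normal_interval(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """log(Φ(b) − Φ(a)) for standardised bounds a < b, numerically stable."""
    a, b = np.broadcast_arrays(np.asarray(a, float), np.asarray(b, float))
    out = np.empty(a.shape, dtype=float)
    # work in whichever tail is better conditioned
    left = (a + b) < 0
    la, lb = log_ndtr(a[left]), log_ndtr(b[left])
    out[left] = lb + np.log1p(-np.exp(np.minimum(la - lb, 0.0)))
    r = ~left
    sa, sb = log_ndtr(-a[r]), log_ndtr(-b[r])
    out[r] = sa + np.log1p(-np.exp(np.minimum(sb - sa, 0.0)))
    return out


def gaussian_start_probability(t0: float, t1: float, mu: float, sigma: float) -> float:
    """Conditional probability of starting in [t0, t1) given not started by t0.

    (Φ(t1) − Φ(t0)) / (1 − Φ(t0)), clamped to [0, 1).  If the survivor
    1 − Φ(t0) underflows the start is forced (probability 1, logged).
    """
    if t1 <= t0:
        raise ValueError("frame must have positive length")
    a, b = (t0 - mu) / sigma, (t1 - mu) / sigma
    log_sf = log_ndtr(-a)
    if not np.isfinite(log_sf) or log_sf < -700:
        log.warning("survivor underflow at t0=%.3f (mu=%.3f, sigma=%.3f)", t0, mu, sigma)
        return 1.0
    p = math.exp(float(_log_normal_interval(a, b)) - float(log_sf))
    return min(max(p, 0.0), 1.0 - 1e-16)


def start_loglik(
    observations: Sequence[StartObservation],
    model: str,
    params: StartParams | GaussianStartParams,
    dt: float | None = None,
    time_density: bool = True,
) -> float:
    """Log-likelihood of starting observations under one model.

    ``dt`` defaults to the frame length of the observations.  Returns
    −inf (with a diagnostic log message) if an observed start has zero
    probability under the model — the model cannot explain the datum.
    """
    if not observations:
        return 0.0
    if dt is None:
        dt = observations[0].t1 - observations[0].t0
    total = 0.0
    for obs in observations:
        if model == GAUSSIAN_START:
            p = gaussian_start_probability(obs.t0, obs.t1, params.mu, params.sigma)
        else:
            mask = parse_start_model(model)
            if set(params.mask) - set(mask):
                raise ValueError(f"params active {params.mask} not within model {mask}")
            p = start_frame_probability(
                rate_from_fractions(obs.rho_clapping, obs.neighbour_fraction, params), dt
            )
        if obs.started:
            if p <= 0.0:
                log.warning(
                    "observed start with zero probability (%s at t=%.3f): "
                    "model %s cannot explain the data",
                    obs.individual_id,
                    obs.t0,
                    model,
                )
                return -math.inf
            total += math.log(p) - (math.log(dt) if time_density else 0.0)
        else:
            total += math.log1p(-p)
    return total


# ---------------------------------------------------------------------------
# Packed arrays for fast repeated evaluation (importance sampling)


@dataclass(frozen=True)
class PackedStartData:
    """Starting observations packed into arrays, pooled across bouts.

    ``xs`` holds the feature rows [1, ρ, ρ², f_nbr] of frames where a
    start occurred; ``xc_sum`` is the column sum of the same features over
    all not-started frames (sufficient because their log-survival is
    linear in the rates).  The Gaussian model additionally needs each
    starter's start frame and each censored individual's observation end.
    """

    dt: float
    xs: np.ndarray  # (n_started, 4)
    xc_sum: np.ndarray  # (4,)
    start_frames: np.ndarray  # (n_started, 2) frame [t0, t1] containing the start
    censor_times: np.ndarray  # (n_censored,) end of observation, no start
    n_observations: int

    @classmethod
    def from_observations(
        cls, observations: Sequence[StartObservation], dt: float
    ) -> "PackedStartData":
        xs, frames, xc = [], [], np.zeros(4)
        cens: dict[str, float] = {}
        for o in observations:
            row = (1.0, o.rho_clapping, o.rho_clapping**2, o.neighbour_fraction)
            if o.started:
                xs.append(row)
                frames.append((o.t0, o.t1))
                cens.pop(o.individual_id, None)
            else:
                xc += row
                cens[o.individual_id] = max(cens.get(o.individual_id, 0.0), o.t1)
        # individuals whose final frame was a start are not censored; the
        # dict may still hold their earlier frames, so rebuild censoring
        started_ids = {o.individual_id for o in observations if o.started}
        censor = [t for iid, t in cens.items() if iid not in started_ids]
        return cls(
            dt=dt,
            xs=np.asarray(xs, float).reshape(-1, 4),
            xc_sum=xc,
            start_frames=np.asarray(frames, float).reshape(-1, 2),
            censor_times=np.asarray(censor, float),
            n_observations=len(observations),
        )

    @classmethod
    def from_bouts(
        cls, bouts: Sequence[Bout], dt: float = 0.1, include_diagonals: bool = False
    ) -> "PackedStartData":
        obs: list[StartObservation] = []
        for bout in bouts:
            obs.extend(make_start_observations(bout, dt, include_diagonals))
        return cls.from_observations(obs, dt)


def rate_loglik_batch(
    data: PackedStartData, lam: np.ndarray, time_density: bool = True
) -> np.ndarray:
    """Vectorised start log-likelihood for many rate-parameter draws.

    ``lam`` has shape (n_draws, 4) in the term order λ1..λ4.  Rows whose
    rate vanishes at any observed start map to −inf.
    """
    lam = np.atleast_2d(np.asarray(lam, float))
    ll = -data.dt * (lam @ data.xc_sum)
    if len(data.xs):
        rates = data.xs @ lam.T  # (n_started, n_draws)
        with np.errstate(divide="ignore"):
            term = np.log(-np.expm1(-rates * data.dt))
        term[rates <= 0] = -np.inf
        ll = ll + term.sum(axis=0)
        if time_density:
            ll -= len(data.xs) * math.log(data.dt)
    return ll


def gaussian_loglik_batch(
    data: PackedStartData, theta: np.ndarray, time_density: bool = True
) -> np.ndarray:
    """Vectorised first-clap-reaction log-likelihood for (mu, sigma) draws.

    Uses the exact telescoped form of the per-frame conditional product:
    each starter contributes the Normal mass of their start frame and each
    censored individual the Normal survival of their observation window,
    both conditioned on a positive response time.
    """
    theta = np.atleast_2d(np.asarray(theta, float))
    mu, sigma = theta[:, 0], theta[:, 1]
    n_ind = len(data.start_frames) + len(data.censor_times)
    log_s0 = log_ndtr(mu / sigma)  # log P(response > 0)
    ll = -n_ind * log_s0
    if len(data.start_frames):
        a = (data.start_frames[:, [0]] - mu) / sigma  # (n_started, n_draws)
        b = (data.start_frames[:, [1]] - mu) / sigma
        ll = ll + _log_normal_interval(a, b).sum(axis=0)
        if time_density:
            ll -= len(data.start_frames) * math.log(data.dt)
    if len(data.censor_times):
        z = (data.censor_times[:, None] - mu) / sigma
        ll = ll + log_ndtr(-z).sum(axis=0)
    return ll
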
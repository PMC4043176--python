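"""Mean-field (deterministic) limit of the applause-contagion model.

Ignoring the clap-count cue, the proportions of susceptible, clapping and
stopped audience members obey

    dS/dt = −λ2·S·(I + R)
    dI/dt =  λ2·S·(I + R) − (γ1 + γ2·R)·I
    dR/dt =  (γ1 + γ2·R)·I

with λ2 the per-second social starting rate and γ1, γ2 *per-second*
stopping rates.  Stopped individuals accelerate stopping (the R term
enters the recovery rate with a positive sign), which distinguishes the
model from a plain SIR epidemic: clapping always sweeps the whole
audience, however small λ2, because susceptibles respond to I + R rather
than to I alone.

Per-clap stopping fits convert to per-second rates through the mean clap
interval: rate = (per-clap probability) / 0.28 s, giving the default
γ1 = 0.008/0.28 ≈ 0.0286 and γ2 = 0.66/0.28 ≈ 2.357.  An alternative
published parameterisation is kept as :data:`CAPTION_PRESET`; its
printed values are mutually inconsistent and are not used by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

__all__ = [
    "OdeParams",
    "CAPTION_PRESET",
    "ode_rhs",
    "integrate",
    "phase_plane",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class OdeParams:
    """Mean-field parameters (per-second rates) and initial composition."""

    lambda2: float = 2.15
    gamma1: float = 0.008 / 0.28
    gamma2: float = 0.66 / 0.28
    s0: float = 0.95
    i0: float = 0.05

    def __post_init__(self) -> None:
        if min(self.lambda2, self.gamma1, self.gamma2) < 0:
            raise ValueError("rates must be non-negative")
        if self.s0 < 0 or self.i0 < 0 or self.s0 + self.i0 > 1 + 1e-12:
            raise ValueError("need S(0), I(0) >= 0 with S(0) + I(0) <= 1")

    @classmethod
    def from_per_clap(
        cls,
        lambda2: float,
        gamma1_per_clap: float,
        gamma2_per_clap: float,
        clap_interval: float = 0.28,
        s0: float = 0.95,
        i0: float = 0.05,
    ) -> "OdeParams":
        """Convert per-clap stopping probabilities to per-second rates."""
        return cls(
            lambda2=lambda2,
            gamma1=gamma1_per_clap / clap_interval,
            gamma2=gamma2_per_clap / clap_interval,
            s0=s0,
            i0=i0,
        )


#: Published phase-plane parameter set (kept verbatim as a preset; the
#: two stopping values are inconsistent with the per-clap conversion).
CAPTION_PRESET = OdeParams(lambda2=2.15, gamma1=0.0011, gamma2=0.094)


def ode_rhs(s: float, i: float, r: float, params: OdeParams) -> tuple[float, float, float]:
    """(dS/dt, dI/dt, dR/dt) at composition (S, I, R)."""
    ds = -params.lambda2 * s * (i + r)
    dr = (params.gamma1 + params.gamma2 * r) * i
    return ds, -ds - dr, dr


def integrate(
    params: OdeParams,
    horizon: float,
    step: float | None = None,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> pd.DataFrame:
    """Integrate the mean-field system over [0, horizon].

    Adaptive 4th/5th-order Runge–Kutta; output on a regular grid of
    spacing ``step`` (default horizon/2000).  Conservation S+I+R = 1 is
    verified to 1e-8 at every output point; violations trigger automatic
    tolerance refinement (logged).
    """
    if horizon <= 0 or (step is not None and step <= 0):
        raise ValueError("horizon and step must be positive")
    step = step or horizon / 2000
    t_eval = np.arange(0.0, horizon + step / 2, step)
    y0 = [params.s0, params.i0, 1.0 - params.s0 - params.i0]

    def rhs(_t, y):
        return ode_rhs(y[0], y[1], y[2], params)

    for attempt in range(4):
        sol = solve_ivp(rhs, (0.0, horizon), y0, t_eval=t_eval, rtol=rtol, atol=atol, method="RK45")
        if not sol.success:
            raise RuntimeError(f"integration failed: {sol.message}")
        drift = np.abs(sol.y.sum(axis=0) - 1.0).max()
        if drift <= 1e-8:
            break
        rtol, atol = rtol / 10, atol / 10
        log.warning("conservation drift %.2e; refining tolerances", drift)
    return pd.DataFrame({"t": sol.t, "S": sol.y[0], "I": sol.y[1], "R": sol.y[2]})


def _di_dt(s: float, i: float, params: OdeParams) -> float:
    r = 1.0 - s - i
    return params.lambda2 * s * (i + r) - (params.gamma1 + params.gamma2 * r) * i


def phase_plane(
    params: OdeParams, grid: int | np.ndarray = 25
) -> dict[str, np.ndarray]:
    """Vector field on the (S, I) simplex and the dI/dt = 0 locus.

    Returns grids of S, I with the (dS/dt, dI/dt) components (NaN outside
    the simplex S + I <= 1), plus the numerically solved locus where
    clapping peaks: λ2·S·(I+R) = (γ1 + γ2·R)·I with R = 1 − S − I.
    """
    axis = np.linspace(0.0, 1.0, grid) if np.isscalar(grid) else np.asarray(grid, float)
    ss, ii = np.meshgrid(axis, axis)
    ds = np.full_like(ss, np.nan)
    di = np.full_like(ss, np.nan)
    inside = ss + ii <= 1.0 + 1e-12
    rr = 1.0 - ss - ii
    ds[inside] = (-params.lambda2 * ss * (ii + rr))[inside]
    di[inside] = (params.lambda2 * ss * (ii + rr) - (params.gamma1 + params.gamma2 * rr) * ii)[inside]
    locus_s, locus_i = [], []
    for s in axis:
        if s <= 0.0 or s >= 1.0:
            continue
        # dI/dt can have several zeros in I (since I + R = 1 − S the
        # growth term is constant in I); scan for every sign change
        i_scan = np.linspace(1e-12, 1.0 - s, 400)
        f = np.array([_di_dt(s, i, params) for i in i_scan])
        signs = np.sign(f)
        for k in np.flatnonzero(signs[:-1] * signs[1:] < 0):
            root = brentq(
                lambda i: _di_dt(s, i, params), i_scan[k], i_scan[k + 1], xtol=1e-12
            )
            locus_s.append(s)
            locus_i.append(root)
    return {
        "S": ss,
        "I": ii,
        "dS": ds,
        "dI": di,
        "locus_S": np.asarray(locus_s),
        "locus_I": np.asarray(locus_i),
    }
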
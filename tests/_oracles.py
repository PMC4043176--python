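"""Independent oracles: brute-force and quadrature reference computations.

Everything here is deliberately naive (per-frame products, dense grids,
explicit enumeration) and shares no code path with the estimators it
checks.
"""

import math

import numpy as np
from scipy.integrate import quad
from scipy.special import logsumexp
from scipy.stats import expon, norm, uniform

from applause.bayes_selection import CandidateModel, loglik_batch

#: integration ranges and densities matching the default priors
_PRIOR_GRID = {
    "lam": (0.0, 30.0, expon(scale=1.0)),
    "gam": (0.0, 1.0, uniform(0.0, 1.0)),
    "mu": (0.0, 10.0, uniform(0.0, 10.0)),
    "sigma": (0.01, 5.0, uniform(0.01, 4.99)),
    "m": (1.0, 50.0, uniform(1.0, 49.0)),
    "s": (0.01, 5.0, uniform(0.01, 4.99)),
}


def _axis(name: str, n: int):
    key = name.rstrip("1234") if name[-1] in "1234" else name
    lo, hi, dist = _PRIOR_GRID[key]
    x = np.linspace(lo, hi, n)
    w = np.full(n, x[1] - x[0])
    w[[0, -1]] /= 2  # trapezoid weights
    return x, np.log(w) + dist.logpdf(x)


def grid_evidence(model: CandidateModel, data, n_grid: int = 2001) -> float:
    """Dense trapezoid quadrature of the evidence integral (1–2 params)."""
    names = model.param_names
    if len(names) == 1:
        x, logw = _axis(names[0], n_grid)
        ll = loglik_batch(model, data, x[:, None])
        return float(logsumexp(ll + logw))
    if len(names) == 2:
        n = max(401, n_grid // 5)
        x1, lw1 = _axis(names[0], n)
        x2, lw2 = _axis(names[1], n)
        g1, g2 = np.meshgrid(x1, x2, indexing="ij")
        theta = np.column_stack([g1.ravel(), g2.ravel()])
        ll = loglik_batch(model, data, theta).reshape(n, n)
        return float(logsumexp(ll + lw1[:, None] + lw2[None, :]))
    raise ValueError("grid oracle covers 1- and 2-parameter models only")


def brute_force_start_loglik(observations, lam2: float, dt: float) -> float:
    """Frame-by-frame product for the pure linear starting model, in the
    event-density convention (started frames contribute log(p/dt))."""
    total = 0.0
    for o in observations:
        p = 1.0 - math.exp(-lam2 * o.rho_clapping * dt)
        total += math.log(p / dt) if o.started else math.log(1.0 - p)
    return total


def geometric_stop_loglik(clap_counts, gamma1: float) -> float:
    """Closed form for the constant stopping model: each individual's clap
    count is geometric, P(n) = (1−γ1)^(n−1)·γ1."""
    return sum(
        (n - 1) * math.log(1.0 - gamma1) + math.log(gamma1) for n in clap_counts
    )


def normal_interval_hazard(t0: float, t1: float, mu: float, sigma: float) -> float:
    """Conditional probability of a Normal variate falling in [t0, t1)
    given it exceeds t0, by adaptive quadrature of the density."""
    dens = norm(mu, sigma).pdf
    num, _ = quad(dens, t0, t1)
    den, _ = quad(dens, t0, mu + 12 * sigma)
    return num / den


def clap_count_pmf(gamma3: float, n_max: int, n_top: int) -> np.ndarray:
    """Enumerated pmf of the clap count under the pure clap-count model:
    P(n) = (γ3·n/n_max) · Π_{k<n} (1 − γ3·k/n_max), clamped hazards."""
    pmf = np.zeros(n_top)
    surv = 1.0
    for n in range(1, n_top + 1):
        h = min(1.0, gamma3 * n / n_max)
        pmf[n - 1] = surv * h
        surv *= 1.0 - h
    return pmf
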
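"""Bayesian model comparison by importance sampling from the prior.

The evidence (marginal likelihood) of a candidate hazard model is the
likelihood integrated over a broad prior on its free parameters,

    P(D | M) = ∫ P(D | φ, M) P(φ | M) dφ,

estimated by averaging exp(log-likelihood) over N prior draws, repeated
over independent replicates to attach a Monte-Carlo standard error.  Model
ranking normalises evidences into relative posterior probabilities under
equal model priors, and flags pairs closer than two combined standard
errors as unresolved — the trigger for doubling N.

Default priors (recorded in every result and configurable per call):
rates λi ~ Exponential(mean 1/s); per-clap probabilities γi ~ Uniform(0,1);
μ ~ Uniform(0,10 s); σ and s ~ Uniform(0.01,5); m ~ Uniform(1,50 claps).
They are weakly informative and deliberately favour no model over
another.

Point estimates ("posterior means") come from the self-normalised
importance-sampling estimator with weights proportional to the likelihood
at prior draws.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from . import starting_models as sm
from . import stopping_models as pm
from .starting_models import PackedStartData
from .stopping_models import PackedStopData

__all__ = [
    "Prior",
    "CandidateModel",
    "EvidenceEstimate",
    "PosteriorSummary",
    "default_prior",
    "model_from_name",
    "enumerate_models",
    "estimate_evidence",
    "rank_models",
    "posterior_mean",
    "select_model",
]


@dataclass(frozen=True)
class Prior:
    """Independent per-parameter prior: names plus frozen distributions."""

    names: tuple[str, ...]
    dists: tuple[object, ...]  # frozen scipy.stats distributions

    def __post_init__(self) -> None:
        if len(self.names) != len(self.dists):
            raise ValueError("names and dists must align")

    @property
    def dim(self) -> int:
        return len(self.names)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.dim == 0:
            return np.empty((n, 0))
        return np.column_stack([d.rvs(size=n, random_state=rng) for d in self.dists])

    def mean(self) -> np.ndarray:
        return np.array([d.mean() for d in self.dists])

    def describe(self) -> dict[str, str]:
        return {name: str(d.kwds or d.args) + f" ({d.dist.name})" for name, d in zip(self.names, self.dists)}


_PRIOR_FACTORIES: dict[str, Callable[[], object]] = {
    "lam": lambda: stats.expon(scale=1.0),
    "gam": lambda: stats.uniform(0.0, 1.0),
    "mu": lambda: stats.uniform(0.0, 10.0),
    "sigma": lambda: stats.uniform(0.01, 4.99),
    "m": lambda: stats.uniform(1.0, 49.0),
    "s": lambda: stats.uniform(0.01, 4.99),
}


@dataclass(frozen=True)
class CandidateModel:
    """One start- or stop-family hypothesis: which hazard terms are active."""

    family: str  # "start" | "stop"
    name: str
    mask: tuple[int, ...] = ()
    gaussian: bool = False
    structurally_impossible: bool = False

    @property
    def param_names(self) -> tuple[str, ...]:
        if self.gaussian:
            return ("mu", "sigma") if self.family == "start" else ("m", "s")
        prefix = "lam" if self.family == "start" else "gam"
        return tuple(f"{prefix}{i}" for i in self.mask)

    @property
    def dim(self) -> int:
        return len(self.param_names)


def model_from_name(family: str, name: str) -> CandidateModel:
    if family == "start":
        if name == sm.GAUSSIAN_START:
            return CandidateModel("start", name, gaussian=True)
        return CandidateModel("start", name, mask=sm.parse_start_model(name))
    if family == "stop":
        if name == pm.GAUSSIAN_STOP:
            return CandidateModel("stop", name, gaussian=True)
        mask = pm.parse_stop_model(name)
        return CandidateModel(
            "stop", name, mask=mask, structurally_impossible=set(mask) <= {2, 4}
        )
    raise ValueError(f"unknown family {family!r}")


def enumerate_models(family: str, restricted: bool = False) -> list[CandidateModel]:
    """All 15 non-empty term combinations plus the Gaussian model (16).

    For the *unrestricted* stop family, purely social masks (subsets of
    {γ2, γ4}) are flagged structurally impossible: someone has to stop
    first, with zero probability under such models.  On restricted data
    (claps after the first stop) they are ordinary candidates.
    """
    fmt = sm.format_start_model if family == "start" else pm.format_stop_model
    models = []
    for size in range(1, 5):
        for mask in itertools.combinations(range(1, 5), size):
            model = model_from_name(family, fmt(mask))
            if restricted and model.structurally_impossible:
                model = CandidateModel(
                    model.family, model.name, mask=model.mask, structurally_impossible=False
                )
            models.append(model)
    models.append(
        model_from_name(family, sm.GAUSSIAN_START if family == "start" else pm.GAUSSIAN_STOP)
    )
    return models


def default_prior(model: CandidateModel) -> Prior:
    dists = tuple(
        _PRIOR_FACTORIES[name.rstrip("1234") if name[-1] in "1234" else name]()
        for name in model.param_names
    )
    return Prior(names=model.param_names, dists=dists)


def _expand(model: CandidateModel, theta: np.ndarray) -> np.ndarray:
    """Masked draws (n, dim) → full 4-column parameter matrix."""
    full = np.zeros((len(theta), 4))
    for j, i in enumerate(model.mask):
        if j < theta.shape[1]:
            full[:, i - 1] = theta[:, j]  # unsupplied parameters stay pinned at 0
    return full


def loglik_batch(
    model: CandidateModel,
    data: PackedStartData | PackedStopData,
    theta: np.ndarray,
) -> np.ndarray:
    """Pooled log-likelihood of ``data`` at each parameter draw."""
    theta = np.atleast_2d(np.asarray(theta, float))
    if model.family == "start":
        if not isinstance(data, PackedStartData):
            raise TypeError("start-family model needs PackedStartData")
        if model.gaussian:
            return sm.gaussian_loglik_batch(data, theta)
        return sm.rate_loglik_batch(data, _expand(model, theta))
    if not isinstance(data, PackedStopData):
        raise TypeError("stop-family model needs PackedStopData")
    if model.gaussian:
        return pm.gaussian_stop_loglik_batch(data, theta)
    return pm.stop_rate_loglik_batch(data, _expand(model, theta))


@dataclass(frozen=True)
class EvidenceEstimate:
    """Log marginal likelihood with replicate-based Monte-Carlo error."""

    model: str
    log_evidence: float
    se: float
    n_samples: int
    replicates: int
    replicate_values: tuple[float, ...] = ()
    diagnostic: str = ""


def estimate_evidence(
    model: CandidateModel,
    data: PackedStartData | PackedStopData,
    prior: Prior | None = None,
    n_samples: int = 10_000,
    replicates: int = 8,
    seed: int = 0,
) -> EvidenceEstimate:
    """Importance-sampled evidence: mean and SE over independent replicates.

    Each replicate averages exp(log-likelihood) over ``n_samples`` prior
    draws, aggregated in log space via log-sum-exp.  A model with no free
    parameters has exact evidence (SE 0).  If every draw in every
    replicate is impossible the evidence is −inf with a diagnostic.
    """
    if replicates < 2 and model.dim > 0:
        raise ValueError("need at least 2 replicates for a standard error")
    prior = prior if prior is not None else default_prior(model)
    if prior.dim == 0:
        value = float(loglik_batch(model, data, np.empty((1, 0)))[0])
        return EvidenceEstimate(model.name, value, 0.0, 0, 1, (value,))
    ss = np.random.SeedSequence(seed)
    values = []
    for child in ss.spawn(replicates):
        rng = np.random.default_rng(child)
        theta = prior.sample(rng, n_samples)
        ll = loglik_batch(model, data, theta)
        values.append(float(logsumexp(ll) - math.log(n_samples)))
    values_arr = np.asarray(values)
    if np.all(np.isneginf(values_arr)):
        return EvidenceEstimate(
            model.name, -math.inf, 0.0, n_samples, replicates, tuple(values),
            diagnostic="all prior draws have zero likelihood",
        )
    finite = values_arr[np.isfinite(values_arr)]
    mean = float(values_arr.mean()) if np.all(np.isfinite(values_arr)) else float(finite.mean())
    se = float(finite.std(ddof=1) / math.sqrt(len(finite))) if len(finite) > 1 else math.inf
    diag = "" if np.all(np.isfinite(values_arr)) else "some replicates degenerate"
    return EvidenceEstimate(model.name, mean, se, n_samples, replicates, tuple(values), diag)


def rank_models(estimates: Sequence[EvidenceEstimate]) -> pd.DataFrame:
    """Rank models by log evidence with relative posterior probabilities.

    Assumes equal prior model probabilities.  ``unresolved_with_next``
    flags a model whose evidence differs from the next-ranked one by less
    than twice their combined standard error — a cue to increase the
    number of importance samples.
    """
    if len(estimates) < 2:
        raise ValueError("need at least two models to rank")
    df = pd.DataFrame(
        {
            "model": [e.model for e in estimates],
            "log_evidence": [e.log_evidence for e in estimates],
            "se": [e.se for e in estimates],
            "n_samples": [e.n_samples for e in estimates],
        }
    ).sort_values("log_evidence", ascending=False, kind="stable").reset_index(drop=True)
    lz = df["log_evidence"].to_numpy()
    finite = np.isfinite(lz)
    probs = np.zeros(len(lz))
    if finite.any():
        probs[finite] = np.exp(lz[finite] - logsumexp(lz[finite]))
    df["rel_prob"] = probs
    unresolved = []
    for i in range(len(df)):
        if i + 1 == len(df):
            unresolved.append(False)
            continue
        a, b = df.loc[i, "log_evidence"], df.loc[i + 1, "log_evidence"]
        if np.isneginf(a) and np.isneginf(b):
            unresolved.append(True)  # tied at impossible
            continue
        gap = a - b
        comb = math.hypot(df.loc[i, "se"], df.loc[i + 1, "se"])
        unresolved.append(bool(np.isfinite(gap) and gap <= 2 * comb))
    df["unresolved_with_next"] = unresolved
    return df


@dataclass(frozen=True)
class PosteriorSummary:
    """Self-normalised IS posterior means, sds and effective sample size."""

    model: str
    means: Mapping[str, float]
    sds: Mapping[str, float]
    ess: float
    n_samples: int


def posterior_mean(
    model: CandidateModel,
    data: PackedStartData | PackedStopData,
    prior: Prior | None = None,
    n_samples: int = 10_000,
    seed: int = 0,
) -> PosteriorSummary:
    """Posterior parameter means via likelihood-weighted prior draws.

    Weights are proportional to the likelihood at each draw (importance
    sampling from the prior).  Warns when the effective sample size drops
    below 50.
    """
    prior = prior if prior is not None else default_prior(model)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    theta = prior.sample(rng, n_samples)
    ll = loglik_batch(model, data, theta)
    if np.all(np.isneginf(ll)):
        raise ValueError(f"model {model.name}: zero likelihood at every prior draw")
    logw = ll - logsumexp(ll)
    w = np.exp(logw)
    ess = float(1.0 / np.sum(w**2))
    if ess < 50:
        warnings.warn(
            f"effective sample size {ess:.1f} < 50 for {model.name}; "
            "posterior summaries may be unreliable",
            stacklevel=2,
        )
    means = w @ theta
    variances = w @ (theta - means) ** 2
    return PosteriorSummary(
        model=model.name,
        means=dict(zip(prior.names, means.tolist())),
        sds=dict(zip(prior.names, np.sqrt(np.maximum(variances, 0.0)).tolist())),
        ess=ess,
        n_samples=n_samples,
    )


def select_model(
    data: PackedStartData | PackedStopData,
    family: str,
    restricted: bool = False,
    n_samples: int = 10_000,
    replicates: int = 8,
    seed: int = 0,
    max_doublings: int = 3,
    priors: Mapping[str, Prior] | None = None,
) -> tuple[pd.DataFrame, list[EvidenceEstimate]]:
    """Evidence for every family model, ranked; doubles N while the top
    two models remain unresolved (up to ``max_doublings`` times)."""
    models = enumerate_models(family, restricted=restricted)
    n = n_samples
    for attempt in range(max_doublings + 1):
        estimates = [
            estimate_evidence(
                m,
                data,
                prior=(priors or {}).get(m.name),
                n_samples=n,
                replicates=replicates,
                seed=seed + attempt,
            )
            for m in models
        ]
        table = rank_models(estimates)
        if not table.loc[0, "unresolved_with_next"]:
            break
        n *= 2
    return table, estimates
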
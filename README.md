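# applause

Social contagion in audience applause: who starts clapping when, who
stops, and why the same talk can earn long or short ovations.

Applause spreads through an audience like an infection. Each audience
member is *susceptible* (S) until their first clap, *infected* (I) while
clapping, and *recovered* (R) once they stop. This package implements a
family of individual-level hazard models for starting and stopping,
Bayesian model comparison between them, and the group-level consequences
of the selected model — for researchers in collective behaviour,
social-contagion modelling and behavioural ecology.

## The models

**Starting.** While susceptible, individual *i* starts clapping with
per-second hazard

    rate_i = λ1 + λ2·ρ_clapping + λ3·ρ_clapping² + λ4·f_i

where ρ_clapping is the fraction of the audience already clapping (I+R)
and f_i the clapping fraction of *i*'s seat neighbours. Any subset of
terms defines a candidate model (`"L1"`, `"L2+L4"`, …); a Normal
first-clap reaction-time model (`"G_start"`) completes the family.

**Stopping.** After each clap, an individual stops with probability

    P_stop = γ1 + γ2·ρ_stopped + γ3·n_claps/n_max + γ4·g_i

(ρ_stopped the stopped fraction, n_claps the individual's clap count,
n_max a normalising maximum, g_i the stopped neighbour fraction), plus a
Normal preferred-clap-count model (`"G_stop"`).

**Selection.** Candidate models are compared by marginal likelihood
P(D|M) = ∫ P(D|φ,M) P(φ|M) dφ, estimated by importance sampling from
broad priors with replicate-based Monte-Carlo standard errors. Point
estimates are self-normalised importance-sampling posterior means.

**Dynamics.** A stochastic event-driven simulator (exponential start
waiting times, per-clap stop draws, Normal(0.28 s, 0.09 s) clap
intervals) and its mean-field ODE limit

    dS/dt = −λ2·S·(I+R),   dR/dt = (γ1 + γ2·R)·I

close the loop from individual rules back to group-level curves. Because
susceptibles respond to I+R rather than I, clapping always sweeps the
whole audience — there is no epidemic threshold; the coordination
problem is stopping, not starting.

## Worked example

Generate a synthetic study shaped like the original experiment (six
groups of 20, 20, 20, 18, 16 and 13 students, two talks each), fit the
linear social starting model, and simulate group-level statistics:

```python
import applause as ap

# 12 bouts under the best-fit models (every individual follows them)
bouts = ap.generate_study(
    ap.StudyDesign(n_non_starters=0),
    "L2", ap.StartParams(lam2=2.15),
    "G2+G3", ap.StopParams(gamma2=0.63, gamma3=0.05, n_max=30),
    seed=1,
)

data = ap.PackedStartData.from_bouts(bouts, dt=0.02)
fit = ap.posterior_mean(ap.model_from_name("start", "L2"), data,
                        n_samples=100_000, seed=2)
print(f"lambda2 = {fit.means['lam2']:.2f} +/- {fit.sds['lam2']:.2f} /s")

_, runs = ap.run_ensemble(ap.SimConfig(n_runs=10_000, seed=3))
print(f"mean bout length  {runs.duration.mean():.2f} s")
print(f"mean stop spread  {runs.stop_spread.mean():.2f} s")
```

Output:

```
lambda2 = 2.33 +/- 0.16 /s
mean bout length  5.51 s
mean stop spread  2.51 s
```

The fitted rate recovers the generating value 2.15 /s within its
posterior spread: each new clapper raises everyone else's start hazard
by 2.15/N per second, so a 20-person audience goes from first to last
clapper in about (2/λ2)·H₁₉ ≈ 3.3 s. The simulated stop spread of
~2.5 s reflects the social stopping cascade; bout length is sensitive to
the clap-count normaliser n_max (see `docs/methods.md`).

The same pipeline is scriptable from a shell:

```
applause synth --seed 1 --out study/
applause select --family start --data study/bouts.csv --out ranking.json
applause ode --out ode/
```

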
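# Methods

## The event-history representation

A bout is a set of per-individual records: start time, stop time and
individual clap times, all relative to the bout's first clap (the time
origin; the end of the stimulus itself is not reliably observable, so
the analysis of starting behaviour conditions on the first clap and the
initiator contributes no starting observations). Audience composition
is summarised by ρ_clapping = (I+R)/N and ρ_stopped = R/N, with the full
audience size N as denominator throughout — non-starters occupy seats
and dilute both fractions but are never counted as started or stopped.
Simultaneous events are ordered deterministically by (time, individual
id).

Two observation sets feed the likelihoods:

* **Starting**: one observation per susceptible individual per frame of
  length Δt (default 0.1 s; configurable), from t = 0 until the
  individual starts or, for non-starters, until the bout ends. The
  state snapshot is taken at the frame start and excludes the focal
  individual.
* **Stopping**: one observation per clap, labelled stopped/continued,
  with the stopped fraction evaluated strictly before the clap (an
  individual's own stop never informs its final observation). The
  *restricted* variant keeps only observations whose pre-event stopped
  fraction is positive — the analysis conditioned on stopping having
  been initiated. The restriction is defined on the audience state
  rather than on clock time so that the first stop event itself (which
  no social model can explain) is excluded.

## Likelihood conventions

Rate models convert hazards to frame probabilities by
p = 1 − exp(−rate·Δt). The default log-likelihood uses the
event-density convention: frames containing a start contribute
log(p/Δt). This converges to the continuous-time event-history
likelihood as Δt → 0 and is stable under frame refinement (halving Δt
from 0.05 to 0.025 s changes the total by < 0.5%); the raw
product-of-probabilities convention is available via
`time_density=False`. Within one dataset and Δt the convention shifts
every model's log-likelihood by the same constant, so model comparison
is unaffected.

**Discretisation bias.** Because p is concave in the rate, coarse
frames bias rate estimates upward by roughly rate·Δt/2 at the observed
starts. Measured on pooled 30-study fits of the linear model at its
true value 2.15 /s: 2.219 at Δt = 0.1, 2.167 at 0.05, 2.137 at 0.02.
Fitting pipelines in this package therefore use Δt = 0.02 s, where the
discretisation bias is far below the statistical error (a single
12-bout study estimates λ2 with sd ≈ 0.15 /s). The residual ~+1.5% in
single-study estimates is ordinary finite-sample bias of hazard MLEs
(E[n/A] exceeds the pooled ratio), not discretisation.

Gaussian models use exact conditional Normal masses; per-individual
products telescope, which the vectorised paths exploit. Survivor
underflow (an individual observed far beyond the distribution's
support) forces probability 1 and is logged.

A stopping model whose terms all vanish when nobody has stopped
(subsets of {γ2, γ4}) assigns probability zero to the bout's first stop:
its likelihood on unrestricted data is −inf, and the enumeration flags
it as structurally impossible rather than silently dropping it.

## Priors and model comparison

The original prior specifications are not available, so the priors are
this package's design choice, recorded in every result and configurable
per call:

| parameter | prior | rationale |
|---|---|---|
| rates λi | Exponential(mean 1 /s) | observed social rates are O(1)/s |
| per-clap γi | Uniform(0, 1) | full probability range |
| μ (reaction time) | Uniform(0, 10 s) | covers observed latencies |
| σ, s | Uniform(0.01, 5) | strictly positive, broad |
| m (claps) | Uniform(1, 50) | covers observed bout lengths |

Evidence is estimated per model by importance sampling from the prior:
log Ẑ = logsumexp(loglik) − log N over N draws, repeated across 8
independent replicates; the mean and its standard error over replicates
are reported, and ranking flags adjacent models within two combined
standard errors as unresolved (triggering doubling of N up to a cap).
Posterior means and sds are self-normalised importance-sampling
estimates; an effective sample size below 50 raises a warning.

**A calibration caveat.** On 12-bout synthetic studies (~200 start
events) the competing cues ρ, ρ² and the neighbour fraction are nearly
collinear, and under the Exponential(1) prior the Occam penalty for
adding a redundant rate term is only about one nat. Consequently the
true generating model is ranked strictly first in ~70–75% of replicate
studies rather than nearly always — the winner virtually always
*contains* the generating term, but supersets overtake it whenever the
redundant direction captures ~1σ of noise. Sharper priors or larger
studies would sharpen selection; the defaults favour breadth.

## Synthetic studies

`generate_study` emulates the experimental design: group sizes (20, 20,
20, 18, 16, 13), three seating rows filled as evenly as possible, two
talks per group with persistent identities and seats, a truncated
Normal(2.1 s, 0.6 s) pre-applause latency, and by default 3 of the 107
participants who never clap (drawn once per study; they keep their
seats and so enter neighbour denominators). Starting uses a
competing-exponentials event loop (hazards are constant between start
events, so the race is exact for all rate models); Gaussian starts are
sampled directly and re-anchored at the minimum. Stopping is the
clap-by-clap event loop with the full model surface, including
neighbour cues on the seating grid.

Parameter-recovery and model-selection experiments set the non-starter
count to zero: a forced non-starter is not data generated under the
fitted model (it has hazard zero where the likelihood expects a
susceptible), and including such individuals biases the recovered
social rate downward by ~20%. With the clean design, pooled recovery
is unbiased (40-study pooled fits: λ2 → 2.17, γ2 → 0.624, γ3 → 0.0497
at generating values 2.15, 0.63, 0.05).

Individual consistency — the same people clapping early in both talks —
is injected by re-dealing each bout's timing bundles (start, claps,
stop) to individuals via a Plackett–Luce draw whose weights share a
per-individual latent eagerness across a group's talks. A
Plackett–Luce order is the arrival order of an exponential race with
proportional hazards, so this is a multiplicative start-hazard frailty
that leaves every group-level curve exactly unchanged; effect 0 gives
independent orders (likelihood models remain well specified) and effect
1 identical orders (the deterministic frailty limit).
`calibrate_consistency_effect` bisects the effect to hit a target
median cross-talk Spearman ρ (effect ≈ 0.6 reproduces the observed
ρ ≈ 0.53).

What the generator does *not* emulate: talk-quality differences (none
were observed), clap-volume cues, restarting after stopping, and any
real-audience heterogeneity beyond the injected frailty. Passing
recovery tests therefore demonstrate internal consistency of the
pipeline, not correctness of the model for real audiences.

## Simulator and mean-field limit

The simulator follows the two-stage scheme: start times from the
cumulative exponential race (stage k has total rate λ2·(N−k)·k/N — each
susceptible carries hazard λ2·(I+R); the literal proportion-product
reading, which stretches a 20-person start spread to ~66 s, is kept
behind `literal_proportion_rates=True` for comparison), then clap-by-
clap stop draws with Normal(0.28 s, 0.09 s) intervals truncated at
0.01 s. Expected start spread is (2/λ2)·H_{N−1} (partial fractions of
the stage rates), which the ensemble reproduces within Monte-Carlo
error.

Defaults are the best-fit parameters: λ2 = 2.15 /s, γ2 = 0.63,
γ3 = 0.05 per clap, n_max = 30, N = 20. At these values a 10,000-run
ensemble gives mean start spread 3.31 s, stop spread 2.50 s and bout
length 5.50 s. Bout length is the statistic most sensitive to n_max
(first-stop initiation scales like √n_max): the observed 6.1 s is
matched by n_max ≈ 45–50, plausibly the actual maximum individual clap
count behind the normaliser, which was never printed; n_max = 30 is
retained as the documented default and logged with every fit.

The mean-field ODEs replace per-clap stopping by per-second rates
γ/0.28 (the mean clap interval). Two systematic gaps separate the
discrete process from this limit: the discrete hazard corresponds to
rate −ln(1−p)/0.28, and each individual's first stop opportunity
arrives at their first clap rather than after an exponential wait —
both errors scale with the per-clap probability. Simulator/ODE
agreement is therefore verified in the small-probability regime
(γ2 = 0.1 per clap: sup-norm 1.6% at N = 2000; at the best-fit
γ2 = 0.66 the gap is ~16%). Ensemble runs are aligned at the
5%-started crossing before averaging because the single-initiator
takeoff time has O(1/λ2) jitter that no audience size removes. The
published per-second phase-plane parameter set is internally
inconsistent (it lists two different values for the social rate) and is
kept only as `CAPTION_PRESET`; defaults use the per-clap conversion.

Integration uses adaptive RK45 at rtol 1e-10 with conservation
S+I+R = 1 verified to 1e-8 at every output point (tolerances refine
automatically on violation). The dI/dt = 0 locus is found by scanning
each S-slice for sign changes and polishing with Brent's method — the
growth term λ2·S·(I+R) = λ2·S·(1−S) is constant in I, so slices
typically carry zero or two roots.

A note on the quadratic comparison (λ3 = 4.0 /s replacing the linear
term, stopping model unchanged): the quadratic cue makes the main
infection wave much sharper (median half-to-full time 1.05 s vs 1.51 s
for the linear model) but its takeoff from a single clapper is slow
(hazard λ3/N² initially), during which early starters accrue clap-count
stopping hazard; as a result sustained all-clapping episodes are *less*
frequent than under the linear model at these parameters. The package
asserts the robust wave-sharpness contrast.

## Analysis conventions

Interval statistics follow the observational definitions: bout length =
first start to last stop; start (stop) spread = first to last start
(stop); standard errors are sample sd/√(bouts). Median ± IQR S/I/R
curves use absolute time from the first clap with no warping. The
claps-per-person figure compares the across-run distribution of per-run
means with a Poisson pmf matched to the same mean (the simulated
distribution is over-dispersed, variance ratio ≈ 1.3) and reports, for
supplied observed bout means, membership of the central 95% interval.

The individual-consistency test computes, per group, the Spearman
correlation between the two talks' start-order (and stop-order) ranks
over shared starters (groups with fewer than three are excluded and
logged); the statistic is the pooled median ρ. The null distribution
permutes one talk's ranks independently within each group
(vectorised), and p is the add-one-corrected fraction of null medians
at least as large as the observed one. This permutation scheme is this
package's construction; under zero injected effect its p-values are
uniform by design, which the test suite checks.

## Problem sizes

Default experiment sizes keep every advertised computation on a single
CPU in minutes: 10,000-run simulation ensembles for group-level
statistics, 10⁵ importance samples (8 replicates) for evidence and
posterior summaries on 12-bout studies, 50 replicate studies for
selection calibration, and N = 2000 audiences for the mean-field
comparison. All randomness flows from explicit integer seeds through
`numpy.random.SeedSequence`; identical seeds give bit-identical
results.

## Known limitations

* Per-clap stopping probabilities are clamped to [0, 1]; "rates" larger
  than ~0.5/clap leave the regime where the per-second conversion and
  the ODE limit are quantitatively accurate.
* n_max is a genuine free constant of the clap-count cue; fits report
  it and bout-length predictions depend on it.
* The evidence estimator samples from the prior; for sharply peaked
  posteriors (large datasets) its effective sample size decays and
  replicate doubling or narrower proposal priors become necessary.
* Neighbour effects use seat adjacency (optionally diagonal) on a
  rectangular grid; real rooms are messier.
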
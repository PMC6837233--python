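# Methods

## Population model

Abundance follows a deterministic, age- and sex-aggregated generalized
logistic model on an annual step:

    N_{t+1} = N_t + N_t r_max [1 − (N_t/K)^z] − R_t,

where `R_t` is the total removal (landed catch times a struck-and-lost
factor).  Growth is applied first and removals subtracted afterwards, exactly
as the recursion is written; no mid-year mortality split is attempted.  The
population is assumed to be at equilibrium (`N_1830 = K`) before the onset of
coastal whaling in Brazil, removals end in 1972, and every trajectory is
projected to 2030 under zero future removals.  The model has no process
error, no age/sex structure and no time-varying `K`; those extensions are
deliberately out of scope.

An extinction floor of 1 whale is imposed: a trajectory that falls below it
is marked invalid, pinned at zero, and its parameter draw receives zero
importance weight.  The floor value is a numerical guard (the dynamics are
undefined for non-positive abundance), not a biological claim.

The shape parameter `z` sets the depletion level at which annual production
`N r_max [1 − (N/K)^z]` peaks, at `(1+z)^(−1/z)` of `K`: 60% for the
conventional z = 2.39, 70% for z = 5.04 and 80% for z = 11.22 (the two
alternative-MSYL scenarios).  A larger `z` delays density dependence, so the
population grows near `r_max` almost until it reaches `K`.

## Catch series

Three ingredients build the annual removal series on the 1830–1972 grid:

- **Annualization.**  Pre-modern records are period totals (e.g. 1830–1839:
  1200–4000 whales).  Each total is spread uniformly over the period's years;
  the record gives no within-period information, and the population-dynamics
  consequences of sub-decadal reallocation are negligible relative to the
  min–max envelope itself.  Fractional annual catches are permitted (the
  modern table already contains fractions).  The small US pelagic catches
  (257 whales) sit in 1840–1849, 1860–1869 and 1894 and are added to both
  envelope ends.
- **Interpolation.**  A single `θ ∈ [0,1]`, shared by all pre-modern periods,
  interpolates `C_t = C_t,min + θ(C_t,max − C_t,min)`.  `θ` has a U[0,1]
  prior and is estimated jointly with the population parameters.
- **Struck-and-lost correction.**  Scalar era factors multiply the landed
  catches: pre-modern `N(1.71, 0.073²)` and modern `N(1.0185, 0.0028²)`, both
  truncated below at 1 (a loss factor cannot be less than one; the truncation
  is numerically irrelevant at 9+ standard deviations).  Factors are sampled
  once per parameter draw and held constant within their era.  The pre-modern
  factor also covers the 1894 pelagic catch for consistency of era.  Under
  the C-4 scenario a separate early-modern factor applies to 1904–1918
  catches: `factor = 1 + λ` with `λ` half-normal, scale 0.15/1.96 ≈ 0.0765,
  truncated to [0, 0.30].  That scale puts exactly 5% of the prior mass above
  a 15% loss rate and none above 30%, the two constraints the scenario is
  defined by (the 95th percentile of a half-normal sits at 1.96σ).  The
  early-modern window follows the scenario description (1904–1918) rather
  than the summary table's 1904–1920.

Modern catches come in four allocation hypotheses — Core, Core+Falkland,
Fringe, Overlap — reflecting uncertainty about which breeding population the
feeding-ground catches belonged to.  The digitized tables reproduce every
printed column total exactly (pre-modern min/max 11 738 / 34 965, pelagic
257, core 31 170, Falkland 219, fringe 31 847, overlap 27 334) and the
pipeline refuses to run if any checksum fails.

## Priors and likelihood

Reference-case priors: `r_max ~ U[0, 0.118]` (upper bound from humpback life
history), `N_2008 ~ U[500, 40 000]`, `θ ~ U[0,1]`, plus the loss-rate priors
above.  The D-7 scenario replaces the uniform `r_max` prior with an
informative one specified only by its moments: mean 8.6%/yr, 95% interval
5–11.4%/yr, hard upper bound 11.8%/yr.  It is implemented as
`N(0.086, 0.0185²)` truncated to [0, 0.118]; the s.d. was chosen analytically
so the truncated distribution places ≈95% of its mass in [0.05, 0.114].  The
family is a design choice — the constraints do not identify one — and any
similarly-shaped unimodal prior changes the D-7 posterior negligibly because
the abundance data dominate `r_max`.

`K` is not sampled: given `(r_max, θ, SLR, N_recent)` it is solved by
bisection so the projection hits `N_recent` in the anchor year (2008; 2012
under D-1).  Abundance in the anchor year is strictly increasing in `K` for
fixed everything-else (verified numerically in the tests), so bisection is
exact; the bracket is `[N_recent, 5×10⁵]` with doubling expansion, iterated
to a relative width below 1e-11, and the solve-then-project round trip
reproduces `N_recent` to better than 1e-6 relative.  A draw whose target is
unattainable is rejected (zero weight), not an error.

Absolute estimates `N̂_y` (2008: 14 264, CV 0.084; 2012: 20 389, CV 0.071)
enter as lognormal terms: `ln N̂_y ~ N(ln N_y, σ_y²)` with
`σ = sqrt(ln(1+CV²))`.  A relative index `I_t` satisfies
`ln I_t ~ N(ln q + ln N_t, σ_t²)` with unknown catchability `q`; integrating
`ln q` out under a flat prior gives the marginal term

    −(n−1)/2 · ln 2π − Σ ln σ_t − ½ ln W − ½ Σ w_t (e_t − ē)²,

with `e_t = ln I_t − ln N_t`, `w_t = σ_t⁻²`, `W = Σ w_t` and `ē` the weighted
mean residual.  The form was re-derived from the stated assumptions and is
verified against numerical quadrature over `ln q` to 1e-6 relative in the
tests.  All additive constants are retained so marginal likelihoods are
comparable across scenarios fitted to the same data.  Consequences worth
knowing: a single-observation index contributes a constant (the free `q`
absorbs it), and the whole term is invariant to rescaling an index series.

The genetic constraint scenarios (G-1, G-2) multiply the likelihood by an
indicator `N_min ≥ N_floor`, with `N_floor` equal to three times the
surviving mtDNA haplotype count (54 haplotypes → 162; 5 WSA-unique → 15).
BG1 and BG2 are never fitted together (they share source data).

## Inference

Plain SIR: 2×10⁵ independent prior draws per scenario (the original run
states only its 10⁴ posterior draws; 2×10⁵ keeps the effective sample size in
the thousands and makes posterior medians stable to <2% across seeds, which
the suite checks), weights equal to the likelihood, multinomial resampling
with replacement down to 10⁴ posterior draws.  Weight diagnostics (effective
sample size `(Σw)²/Σw²` and largest weight share) are reported with every
run.  The mean weight estimates the scenario's marginal likelihood; model
probabilities are the normalized marginals under equal prior model
probabilities across the nine comparable scenarios
{RC, D-1, D-7, C-4, C-5, C-6, C-7, M-1, M-2}.  Scenarios that change the
fitted data (D-2…D-6) have non-comparable likelihoods, C-1…C-3 deliberately
discard plausible inputs, and G-1/G-2 duplicate the RC posterior, so all are
excluded; the code enforces comparability by hashing the observation set and
refusing to average across different hashes.  The averaged posterior pools
whole parameter vectors: a member is sampled by its probability, then one of
its posterior draws.  All randomness flows from one seed through per-scenario
child streams, so results do not depend on the order scenarios run.

## Synthetic data and what the tests show

The generator projects a known trajectory and observes it exactly as the
model assumes: lognormal noise at the real observation years and CVs,
indices scaled by a known `q`.  Default truth: r_max = 0.09, z = 2.39,
θ = 0.5, the real removal template at prior-mean loss factors, and a true
2008 abundance anchored at the survey point estimate (14 264 whales) with
`K` derived by the backwards solve (≈28 600, trajectory minimum ≈400 whales
in 1958).  Anchoring matters: the deterministic model recovers quickly at
these growth rates, so a truth that is still mid-recovery in 2008 — the
regime in which the data identify `K` and `r_max`, and the regime the real
population was in — necessarily passes within a few hundred whales of
extinction, exactly as the fitted trajectories do.  Noise is
mean-unbiased (`N̂ = N exp(σε − σ²/2)`), a documented convention choice; the
likelihood is median-unbiased, but at the survey CVs (≤0.1 for the
informative series) the σ²/2 offset is a ≲0.5% effect, far below posterior
spread.  Parameter recovery over 50 replicates (2×10⁴ prior draws each —
enough for stable medians at synthetic-data precision while keeping the
experiment to a couple of minutes) checks that nominal 95% intervals for `K`
cover the truth at a binomially-consistent rate and that median bias in `K`
is under 10%.

Because the generator implements the model's own assumptions, these tests
demonstrate self-consistency of the inference machinery, not robustness: real
surveys have correlated effort, possible trend in catchability and
non-lognormal error, and the catch record's annualization is conventional.
None of that is probed by the synthetic studies.

## Numerical conventions and limitations

- Quantiles use inclusive linear interpolation (numpy default); reported
  tables round abundances to whole whales and rates to 3 decimals while
  full-precision draws are always written alongside.
- Trajectory storage: full annual trajectories are kept for posterior
  (resampled) draws only; prior-stage evaluation records only the years the
  likelihood and summaries need.
- The krill arithmetic is deliberately crude by construction: population ×
  daily ingestion rate × 120-day season, against a fixed 60.3 M t biomass
  estimate, with no propagation of the biomass CV.
- Known limitations: no post-1972 anthropogenic mortality (entanglement, ship
  strikes), so current status is if anything overestimated; catch allocation
  hypotheses are discrete alternatives rather than a continuous mixing model;
  the deterministic dynamics make the valid/invalid boundary in parameter
  space sharp, which is handled by zero-weighting rather than smoothing.
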
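# Methods

## Splicing kinetics and the log-additivity argument

The splicing decision is modelled as a linear reaction network: precursor
`x0` produced at constant rate `c`, converted into six species (inclusion,
skipping, full / first / second intron retention, pooled non-canonical) with
rates `r_i`, each degraded at rate `d_i`:

    dx0/dt = c - (r1 + ... + r6) x0
    dxi/dt = r_i x0 - d_i x_i

At steady state the measurable frequencies are `p_i = K_i / sum(K)` with
`K_j = r_j / d_j` and `K_3 = 1 + r_3/d_3` — the unspliced precursor is pooled
into the full-intron-retention species because a read spanning retained
introns cannot distinguish the two. `steady_state_frequencies` implements
this closed form; `integrate_ode` (LSODA, rtol 1e-10) is kept as an
independent oracle and the two are required to agree to 1e-6 on random rate
sets.

A mutation is modelled as a multiplicative perturbation of the `K_i`. On
frequencies the induced fold change depends on all other rates (the
normalisation couples everything); on ratios `R_i = K_i / K_1` perturbations
multiply exactly, so log ratios are additive across mutations. This is an
algebraic identity, tested exactly, and it is the entire justification for
the linear regression below. Natural logarithms are used internally; export
tables add log2 columns.

## Regression model

For each non-reference isoform `i`, each minigene contributes one equation

    ln(p_i / p_1) = alpha_i + sum_{m in minigene} beta_{m,i} + noise.

`MutationEffectRegressor` solves the five systems with LSQR
(atol = btol = 1e-10, iteration cap 20 000) on the sparse binary incidence
matrix with an appended intercept column. Design choices:

- **Free intercept.** `alpha_i` is not pinned to the wild-type mean; the
  ~591 all-zero wild-type rows anchor it while still averaging over their
  noise.
- **Replicates.** Each replicate is fitted independently and the betas
  averaged; per-replicate estimates are retained because the z-score and
  synergy statistics need them. Mutations whose every carrier minigene
  drops out of some replicate are flagged and excluded from calling.
- **Zero frequencies.** Observed zero (or filtered-out) frequencies are
  floored at `1/(total_pairs + 1)` before taking logs. The floor is
  depth-aware — it vanishes as coverage grows — and keeps
  inclusion-abolished minigenes in the system rather than discarding them.
- **Identifiability.** Columns that are exact duplicates (mutations that
  only ever co-occur) are flagged unidentifiable; LSQR returns their
  minimum-norm split, which is excluded from downstream calls.

A caveat worth knowing: the problem is only as well-posed as the ratio of
minigenes to distinct mutations. At the default scale (5 791 minigenes,
≤ 2 121 mutation labels, ratio ≈ 2.7 — comparable to a real screen) the
system is comfortably overdetermined. If a library is subsampled so the
ratio approaches 1, coefficient variance explodes; this is ordinary
least-squares behaviour, not a solver artefact, and the package does not
regularise it away.

Inference accuracy is profiled by `leave_out_error_curve`: each mutation
with a single-mutation minigene has that minigene held out, its remaining
occurrences thinned to n = 1, 2, 4, 8, and the model refitted. The SD of the
prediction error decays approximately as `1/sqrt(n)` and stays below the
median-per-mutation baseline at every occurrence level. On synthetic data
the error is measured against the generator's noise-free expectation
(`truth=` argument); against the held-out *observed* minigene — the only
option on real data — the curve carries that measurement's ~3% noise as a
constant floor, which masks the scaling at high occurrence.

## Significance and synergy

z-scores standardise model-predicted single-mutation frequencies against
the wild-type minigene distribution per replicate; Stouffer's unweighted
combination (`sum z / sqrt(R)`) gives the test statistic, converted to a
two-sided normal p and BH-adjusted within each isoform family. Calls
require both |ΔIF| ≥ 0.05 and adjusted p < 0.05; a position is effective
when any of its mutations is.

Synergy compares condition-specific fits: `Delta = beta_KD − beta_ctrl` per
ratio, standardised by the SD (across wild-type minigenes, per replicate)
of the wild-type knockdown log-ratio change. Because the intercept is
wild-type-anchored, `Delta` is automatically relative to the wild-type
response. Calls require BH p < 0.001, |Stouffer z| > 2, the same `Delta`
sign in all replicates, and two exclusions that guard against boundary
effects: splice-site positions (209–210, 298–299, 443–444, 523–524,
689–690; configurable) and mutations whose predicted control frequency of
either isoform in the tested ratio is below 1% — a mutation that abolishes
an isoform on its own leaves no room to measure a knockdown response.

The synergy z is *approximately* standardised, not exactly: for a mutation
occurring in n minigenes the regression averages measurement noise
(deflating z by roughly `1/sqrt(n)`), while mutations sharing their only
minigene with others inherit extra variance. At the default scale the null
z SD is ≈ 1.2 and the 0.1% FDR call rate on null data is far below the
0.5% bound the tests assert; the statistic is calibrated empirically by
simulation, not by its nominal normality.

## Hill fits and profile likelihood

`HillCurveFitter` minimises `sum(((y - y(x)) / sigma)^2)` for
`y(x) = y_max − (y_max − y_min) x^nH / (x^nH + EC50^nH)` with TRF bounded
least squares inside the box y_min ∈ [−0.5, 0], y_max ∈ [0, 0.5],
EC50 ∈ [0.1, 2], nH ∈ [1, 20], using 20 seeded starts (one data-driven,
the rest log-uniform for the scale-like parameters). Confidence intervals
come from profile likelihood: scan a grid per parameter (log-spaced for
EC50 and nH — their profiles are asymmetric — 61 points per side),
re-optimise the rest at each fixed value, and interpolate the crossings of
`chi2_0 + 3.841` (the 95% chi-square quantile with 1 df). During profiling
the box is relaxed by default (nH up to 200): the likelihood frequently
supports steepness values beyond the fitting bound, and profiling inside
the original box would truncate the interval at an arbitrary edge; a flag
restores strict-box profiling. Non-crossing endpoints are reported at the
scan boundary and flagged open.

## Synthetic data generator

The generator defines the benchmark conditions:

- **Library**: 5 200 mutated + 591 wild-type variants, unique random 15-nt
  barcodes. Mutations per mutated variant follow a zero-truncated Poisson
  whose *truncated mean* equals the nominal load (3.6) — parameterising the
  rate directly would give a sample mean of ≈ 3.70. Positions are uniform
  over the 707-nt synthetic reference (a fixed-seed random sequence; the
  package has no claim to any real reporter's sequence), alternative bases
  uniform over the three non-reference bases. At this load ~100% of
  positions are hit by ≥ 10 variants.
- **Effects**: a point-mass-at-zero / Gaussian mixture on the five log
  ratios. Defaults `effect_fraction = 0.4`, `effect_sd = 1.2` were chosen
  to reproduce two dataset-level statistics of real screens of this design:
  roughly 43% of scored mutations significantly change some isoform, and
  ~45% of mutated minigenes shift exon inclusion by more than 10 points.
- **Counts**: Dirichlet-multinomial per minigene and replicate.
  `overdispersion` is the excess-variance parameter ρ (Dirichlet
  concentration 1/ρ; ρ = 0 is exactly multinomial). `calibrate_noise`
  bisects ρ against simulation until the wild-type inclusion SD at the
  target depth (1 000 read pairs) matches 3%, the experimental wild-type
  variation; at that depth ρ ≈ 0.005, i.e. biological/technical scatter
  dominates counting noise about five-fold.
- **Knockdown**: a global log shift on the skipping:inclusion ratio
  (default benchmark: ln 2.4), plus optional per-mutation synergy terms on
  the same ratio, applied only under knockdown.
- **Dose–response**: points on a Hill curve with i.i.d. Gaussian noise.

What the generator does *not* emulate — and therefore what passing tests do
not establish about real data: sequencing errors and misassigned reads
(barcodes are exact outside the dedicated FASTQ fixtures), PCR chimeras and
index hopping, replicate-specific batch effects (replicates are i.i.d.),
position-dependent mutational biases, correlated effects of neighbouring
mutations, and genuine epistasis between mutations (the world is exactly
log-additive by construction, so the regression's model mismatch on real
data is not probed).

## Numerical and scale choices

Benchmarks run at the realistic library scale because the inference quality
is governed by the minigene-to-mutation ratio; the expensive pieces are the
leave-out error curve (~320 refits of the five-ratio system, ~1–2 minutes)
and the Hill CI coverage sweep. Simulated dose–response recovery uses 25
x-values log-spaced on [0.3, 2.0], σ = 0.01, and 20 repeats. Filter
boundaries are strict readings of the quantification rules (exactly 1%
support or exactly 2 read pairs is retained); isoform support filtering is
per minigene by default with a library-wide variant behind a flag, and is
applied before the ≥ 100-pair coverage gate recomputes totals.

## Known limitations

- Indels are accepted as opaque design-matrix labels but never simulated.
- The G-run minimum length (3) is a convention, configurable but untested
  against crosslinking data.
- Profile CIs assume a well-behaved chi-square geometry; for boundary fits
  (nH at 1, constant data) intervals are one-sided and flagged rather than
  corrected.
- The synergy z calibration is empirical (see above); treat tier
  thresholds as ranking devices, not exact error rates.
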
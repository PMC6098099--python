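# mutsplice

Analysis toolkit for massively parallel, barcode-based minigene splicing
screens — the experiments in which a reporter exon with its flanking introns
is randomly mutagenised, thousands of barcoded variants are expressed in
cells, and targeted RNA-seq reads out how each mutation shifts the balance
between splice isoforms (exon inclusion, skipping, intron retention,
non-canonical products).

The central difficulty of such screens is that each minigene carries
*several* mutations (here a mean of 3.6), so every measurement is an
overlay of effects. `mutsplice` implements the full deconvolution pipeline
and ships a synthetic-library generator with planted ground truth, so every
stage has a parameter-recovery test without any sequencing download.

## The model

A kinetic description of the splicing decision — precursor produced at rate
*c*, converted to isoform *i* at rate *r<sub>i</sub>* and degraded at rate
*d<sub>i</sub>* — gives steady-state isoform frequencies

> *p<sub>i</sub>* = *K<sub>i</sub>* / Σ<sub>j</sub> *K<sub>j</sub>*,  with
> *K<sub>j</sub>* = *r<sub>j</sub>*/*d<sub>j</sub>* (and
> *K*₃ = 1 + *r*₃/*d*₃ pooling the unspliced precursor with full intron
> retention, which sequencing cannot distinguish).

Because of the shared normalisation, mutation effects on *frequencies*
depend on the mutational background. On isoform **ratios**
*R<sub>i</sub>* = *p<sub>i</sub>*/*p*₁ = *K<sub>i</sub>*/*K*₁ they do not:
multiplicative effects on rates combine **log-additively**,

> ln *R<sub>i</sub>*(minigene) = α<sub>i</sub> +
> Σ<sub>m ∈ minigene</sub> β<sub>m,i</sub>,

one linear equation per minigene. Solving the five systems (one per
non-reference isoform) by sparse least squares deconvolves single-mutation
effects β from combined measurements. Downstream, the package provides:

- **Significance calling** — model-predicted single-mutation frequencies
  are standardised against the wild-type minigene distribution
  (*z* = (*p* − mean *p*<sup>wt</sup>)/SD *p*<sup>wt</sup>), combined
  across replicates by Stouffer's method, BH-corrected; a mutation is
  *splicing-effective* when |ΔIF| ≥ 5% at FDR < 5%.
- **Synergy analysis** — effects are fitted separately under control and
  RBP-knockdown conditions; Δ = β<sup>KD</sup> − β<sup>ctrl</sup>,
  standardised by the wild-type knockdown response, flags mutations that
  blunt or amplify the knockdown (FDR < 0.1%, |z| > 2, consistent sign).
- **Cooperativity** — Hill fits of ΔPSI versus regulator level with a
  χ²-normalised cost, box constraints and profile-likelihood confidence
  intervals (threshold χ²(0.95, 1 df) = 3.841).
- **SRBS annotation** — motif sites filtered to splice-regulatory binding
  sites (≥60% splicing-effective positions), collapsed across ≥2-nt
  overlaps, and G-run disrupting/extending classification of mutations.

## Worked example

```python
import numpy as np

from mutsplice import (
    calibrate_noise, generate_library, simulate_counts,
    compute_frequencies, fit_effects, crossvalidate,
    significance_table, call_effective,
)
from mutsplice.significance import wt_frequency_stats

# 1. synthetic screen: 5200 mutated + 591 wild-type barcoded minigenes,
#    3 replicates, noise calibrated to 3% wild-type inclusion SD
rho = calibrate_noise(target_wt_sd=0.03, depth=1000, seed=0)
library, truth = generate_library(5200, 591, mean_mutations=3.6, seed=0)
counts = simulate_counts(library, truth, depth=1000, overdispersion=rho,
                         n_replicates=3, seed=1)

# 2. isoform frequencies after the support/coverage filters
freqs, dropped = compute_frequencies(counts)

# 3. single-mutation effects on log isoform ratios by sparse least squares
fit = fit_effects(library, freqs)
planted = np.array([truth.effect[lab][0] for lab in fit.labels])
common = fit.occurrence >= 5
r = np.corrcoef(planted[common], fit.beta[common, 0])[0, 1]
print(f"mutations fitted: {len(fit.labels)}")
print(f"recovery of planted skip-ratio effects (occurrence >= 5): r = {r:.3f}")

# 4. tenfold cross-validation on held-out minigenes
cv, _ = crossvalidate(library, freqs, k=10, seed=2)
print(f"cross-validated inclusion-frequency prediction: r = {cv['incl']:.3f}")

# 5. splicing-effective mutations (|deltaIF| >= 5%, BH FDR < 5%)
table = significance_table(fit, wt_frequency_stats(freqs, library))
table, effective, positions = call_effective(table)
print(f"splicing-effective mutations: {len(effective)} "
      f"in {len(positions)} positions")
```

Output:

```
mutations fitted: 2119
recovery of planted skip-ratio effects (occurrence >= 5): r = 0.977
cross-validated inclusion-frequency prediction: r = 0.943
splicing-effective mutations: 799 in 534 positions
```

The recovery correlation compares inferred β against the *planted* ground
truth — the screen's measurements never see single mutations in isolation
for most positions, yet the regression disentangles them to r ≈ 0.98 once a
mutation occurs in five or more minigenes. The cross-validation number is
the prediction accuracy for *combinations* of mutations in held-out
minigenes. About 40% of mutations are planted as effectful; with
measurement noise at the 3% level the caller recovers them at 5% FDR.

A command-line interface mirrors the library (`mutsplice simulate`,
`quantify`, `barcodes`, `infer`, `cv`, `error-curve`, `call`, `synergy`,
`hill`, `srbs` — see `mutsplice --help`).

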
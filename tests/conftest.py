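"""Shared fixtures: calibrated noise and full-scale simulated screens.

The expensive full-scale simulations (5200 mutated + 591 wild-type
minigenes, three replicates) are session-scoped so the recovery, null and
knockdown tests share them.
"""

import numpy as np
import pytest

from mutsplice.inference import fit_effects
from mutsplice.quantify import compute_frequencies
from mutsplice.simulate import calibrate_noise, generate_library, simulate_counts
from mutsplice.synergy import wt_kd_response

FULL_N_MUTATED = 5200
FULL_N_WT = 591
DEPTH = 1000


@pytest.fixture(scope="session")
def rho_default():
    """Overdispersion calibrated to 3% wild-type inclusion SD at depth 1000."""
    return calibrate_noise(target_wt_sd=0.03, depth=DEPTH, seed=123)


@pytest.fixture(scope="session")
def ctrl_screen(rho_default):
    """Full-scale control-condition screen with planted effects."""
    library, truth = generate_library(FULL_N_MUTATED, FULL_N_WT, 3.6, seed=42)
    counts = simulate_counts(library, truth, depth=DEPTH,
                             overdispersion=rho_default, n_replicates=3,
                             condition="ctrl", seed=4242)
    freqs, _ = compute_frequencies(counts)
    fit = fit_effects(library, freqs)
    return {"library": library, "truth": truth, "freqs": freqs, "fit": fit,
            "rho": rho_default}


@pytest.fixture(scope="session")
def kd_screen(rho_default):
    """Two-condition screen with a planted 2.4-fold knockdown shift."""
    library, truth = generate_library(
        FULL_N_MUTATED, FULL_N_WT, 3.6, seed=77,
        kd_global=float(np.log(2.4)), synergy_fraction=0.15, synergy_sd=0.8)
    fc, _ = compute_frequencies(simulate_counts(
        library, truth, depth=DEPTH, overdispersion=rho_default,
        n_replicates=3, condition="ctrl", seed=771))
    fk, _ = compute_frequencies(simulate_counts(
        library, truth, depth=DEPTH, overdispersion=rho_default,
        n_replicates=3, condition="kd", seed=772))
    fit_c = fit_effects(library, fc)
    fit_k = fit_effects(library, fk)
    wt_resp = wt_kd_response(fc, fk, library)
    return {"library": library, "truth": truth, "freqs_ctrl": fc,
            "freqs_kd": fk, "fit_ctrl": fit_c, "fit_kd": fit_k,
            "wt_response": wt_resp}
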
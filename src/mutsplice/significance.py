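"""Significance calling for single-mutation splicing effects.

Model-predicted single-mutation isoform frequencies are converted to
z-scores against the wild-type minigene distribution,

    z = (p_i^mutation - mean(p_i^wt)) / SD(p_i^wt),

independently per replicate.  Replicate z-scores are averaged for effect
size and Stouffer-combined (sum z / sqrt(R)) for significance; the combined
z is converted to a two-sided normal p value and corrected for multiple
testing by Benjamini-Hochberg within each isoform family.  A mutation is
called splicing-effective when, for at least one isoform, |deltaIF| >= 5
percentage points and the adjusted p < 0.05; a position is effective when
at least one of its mutations is.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm

from .kinetics import ISOFORMS
from .inference import EffectFit, predict_frequencies_batch
from .simulate import Mutation

__all__ = [
    "zscore",
    "stouffer",
    "bh_adjust",
    "wt_frequency_stats",
    "significance_table",
    "call_effective",
]


def zscore(p_mut, wt_mean, wt_sd):
    """Standardise a predicted frequency against the wild-type distribution."""
    wt_sd = np.asarray(wt_sd, dtype=float)
    if np.any(wt_sd <= 0):
        raise ValueError("wild-type SD must be positive")
    return (np.asarray(p_mut, dtype=float) - wt_mean) / wt_sd


def stouffer(z_list):
    """Stouffer-combined z and its two-sided normal p value."""
    z = np.asarray(z_list, dtype=float)
    z = z[np.isfinite(z)]
    if z.size == 0:
        raise ValueError("at least one finite z-score is required")
    zc = z.sum() / np.sqrt(z.size)
    return float(zc), float(2.0 * norm.sf(abs(zc)))


def bh_adjust(p_list) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (monotone, capped at 1)."""
    p = np.asarray(p_list, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def wt_frequency_stats(freqs: pd.DataFrame, library) -> pd.DataFrame:
    """Per-replicate mean and SD of each isoform frequency over wt minigenes."""
    wt_bc = {v.barcode for v in library if v.is_wt}
    sub = freqs[freqs["barcode"].isin(wt_bc)]
    if sub.empty:
        raise ValueError("no wild-type minigenes present in the frequency table")
    rows = []
    for rep, grp in sub.groupby("replicate"):
        m = grp[list(ISOFORMS)].mean().to_numpy()
        s = grp[list(ISOFORMS)].std(ddof=1).to_numpy()
        rows.append((rep, *m, *s))
    cols = (["replicate"] + [f"mean_{iso}" for iso in ISOFORMS]
            + [f"sd_{iso}" for iso in ISOFORMS])
    return pd.DataFrame(rows, columns=cols)


def significance_table(fit: EffectFit, wt_stats: pd.DataFrame) -> pd.DataFrame:
    """Per mutation x isoform z-scores, Stouffer combination and BH-adjusted p.

    Only mutations present and identifiable in all replicates are scored.
    ``delta_if`` is the replicate-mean difference between the
    model-predicted single-mutation frequency and the wild-type mean.
    """
    reps = list(wt_stats["replicate"])
    keep = fit.present_all & fit.identifiable
    labels = [lab for lab, k in zip(fit.labels, keep) if k]
    idx = np.nonzero(keep)[0]
    n_lab = len(labels)

    z_reps = np.empty((len(reps), n_lab, len(ISOFORMS)))
    dif_reps = np.empty_like(z_reps)
    incidence = np.zeros((n_lab, len(fit.labels)))
    incidence[np.arange(n_lab), idx] = 1.0
    for r, rep in enumerate(reps):
        pred = predict_frequencies_batch(fit, incidence, replicate=rep)
        row = wt_stats[wt_stats["replicate"] == rep].iloc[0]
        mean = row[[f"mean_{iso}" for iso in ISOFORMS]].to_numpy(dtype=float)
        sd = row[[f"sd_{iso}" for iso in ISOFORMS]].to_numpy(dtype=float)
        dif_reps[r] = pred - mean
        z_reps[r] = zscore(pred, mean, sd)

    records = []
    for i, iso in enumerate(ISOFORMS):
        z_c = z_reps[:, :, i].sum(axis=0) / np.sqrt(len(reps))
        p = 2.0 * norm.sf(np.abs(z_c))
        p_adj = bh_adjust(p)
        for j, lab in enumerate(labels):
            records.append({
                "label": lab,
                "isoform": iso,
                **{f"z_rep{rep}": z_reps[r, j, i] for r, rep in enumerate(reps)},
                "z_mean": z_reps[:, j, i].mean(),
                "z_stouffer": z_c[j],
                "p": p[j],
                "p_adj": p_adj[j],
                "delta_if": dif_reps[:, j, i].mean(),
            })
    return pd.DataFrame.from_records(records)


def call_effective(records: pd.DataFrame, min_delta_if: float = 0.05,
                   fdr: float = 0.05):
    """Call splicing-effective mutations and positions.

    A mutation is effective if for at least one isoform |deltaIF| >=
    ``min_delta_if`` and adjusted p < ``fdr``; a position is effective if
    at least one of its (up to three) mutations is.

    Returns ``(records_with_flag, effective_mutations, effective_positions)``.
    """
    rec = records.copy()
    rec["effective"] = (rec["delta_if"].abs() >= min_delta_if) & (rec["p_adj"] < fdr)
    eff = rec.groupby("label")["effective"].any()
    effective_mutations = sorted(eff[eff].index)
    effective_positions = sorted(
        {Mutation.from_label(lab).position for lab in effective_mutations}
    )
    return rec, effective_mutations, effective_positions
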
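"""Mutation x knockdown synergy from condition-specific ratio effects.

Single-mutation effects on log isoform ratios are inferred separately under
control and knockdown conditions; their difference Delta = beta_KD -
beta_ctrl measures how much a mutation reshapes the knockdown response.
Because the free intercept is anchored by the wild-type minigenes, Delta is
already expressed relative to the wild-type knockdown response.  It is
standardised per replicate by the wild-type variation of the knockdown
log-ratio change,

    z = (beta_KD - beta_ctrl) / SD_wt[ln R^KD - ln R^ctrl],

averaged across replicates for effect size and Stouffer-combined for
significance.  Calls require FDR < 0.1%, |z| above a tier threshold
(2 / 3 / 5), consistent Delta sign in all replicates, exclusion of splice-site
positions, and exclusion of mutations that on their own abolish an isoform
(<1% predicted control frequency in either isoform of the tested ratio).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm

from .kinetics import ISOFORMS
from .inference import EffectFit, predict_frequencies_batch
from .quantify import floored_log_ratios
from .significance import bh_adjust
from .simulate import Mutation

__all__ = [
    "SPLICE_SITE_POSITIONS",
    "wt_kd_response",
    "compute_synergy",
    "global_kd_effect",
    "call_synergistic",
]

#: Splice-site positions excluded from synergy calling (donor/acceptor
#: dinucleotides of the three exons on the minigene).
SPLICE_SITE_POSITIONS = frozenset(
    {209, 210, 298, 299, 443, 444, 523, 524, 689, 690}
)

RATIO_NAMES = [f"{iso}_vs_incl" for iso in ISOFORMS[1:]]


def wt_kd_response(freqs_ctrl: pd.DataFrame, freqs_kd: pd.DataFrame, library):
    """Per-replicate wild-type log-ratio change (KD minus ctrl).

    Pairs wild-type minigenes by barcode within each replicate and returns
    a frame with columns ``replicate, barcode`` and the five per-ratio
    changes ``d_log_<ratio>``.
    """
    wt_bc = {v.barcode for v in library if v.is_wt}
    cols = [f"log_ratio_{iso}" for iso in ISOFORMS[1:]]
    out = []
    for cond, freqs in (("ctrl", freqs_ctrl), ("kd", freqs_kd)):
        sub = freqs[freqs["barcode"].isin(wt_bc)]
        lr = floored_log_ratios(sub)
        lr = lr[["barcode", "replicate"] + cols].copy()
        lr["condition"] = cond
        out.append(lr)
    merged = pd.merge(
        out[0], out[1], on=["barcode", "replicate"], suffixes=("_ctrl", "_kd")
    )
    for iso in ISOFORMS[1:]:
        merged[f"d_log_{iso}_vs_incl"] = (
            merged[f"log_ratio_{iso}_kd"] - merged[f"log_ratio_{iso}_ctrl"]
        )
    keep = ["replicate", "barcode"] + [f"d_log_{r}" for r in RATIO_NAMES]
    return merged[keep]


def compute_synergy(fit_ctrl: EffectFit, fit_kd: EffectFit,
                    wt_response: pd.DataFrame) -> pd.DataFrame:
    """Synergy records for every shared mutation and isoform ratio.

    Mutations absent from any knockdown replicate are dropped.  ``delta``
    is the replicate-mean beta_KD - beta_ctrl (natural log).
    """
    reps = [r for r in fit_ctrl.replicates if r in fit_kd.replicates]
    if len(reps) < 2:
        raise ValueError("at least two shared replicates are required")
    shared = sorted(set(fit_ctrl.labels) & set(fit_kd.labels))
    idx_c = np.array([fit_ctrl.index_of(l) for l in shared])
    idx_k = np.array([fit_kd.index_of(l) for l in shared])
    ok = (fit_ctrl.present_all[idx_c] & fit_kd.present_all[idx_k]
          & fit_ctrl.identifiable[idx_c] & fit_kd.identifiable[idx_k])
    shared = [l for l, o in zip(shared, ok) if o]
    idx_c, idx_k = idx_c[ok], idx_k[ok]

    sd_wt = np.empty((len(reps), 5))
    for r, rep in enumerate(reps):
        grp = wt_response[wt_response["replicate"] == rep]
        sd_wt[r] = grp[[f"d_log_{n}" for n in RATIO_NAMES]].std(ddof=1).to_numpy()
    if np.any(sd_wt <= 0):
        raise ValueError("wild-type KD-response SD must be positive")

    records = []
    for i, ratio in enumerate(RATIO_NAMES):
        delta_reps = np.stack([
            fit_kd.beta_reps[fit_kd.replicates.index(rep)][idx_k, i]
            - fit_ctrl.beta_reps[fit_ctrl.replicates.index(rep)][idx_c, i]
            for rep in reps
        ])  # (R, n)
        z_reps = delta_reps / sd_wt[:, i][:, None]
        z_c = z_reps.sum(axis=0) / np.sqrt(len(reps))
        p = 2.0 * norm.sf(np.abs(z_c))
        p_adj = bh_adjust(p)
        signs = np.sign(delta_reps)
        direction_ok = np.all(signs == signs[0], axis=0) & np.all(signs != 0, axis=0)
        for j, lab in enumerate(shared):
            records.append({
                "label": lab,
                "position": Mutation.from_label(lab).position,
                "ratio": ratio,
                "delta": delta_reps[:, j].mean(),
                **{f"z_rep{rep}": z_reps[r, j] for r, rep in enumerate(reps)},
                "z_mean": z_reps[:, j].mean(),
                "z_stouffer": z_c[j],
                "p": p[j],
                "p_adj": p_adj[j],
                "direction_ok": bool(direction_ok[j]),
            })
    return pd.DataFrame.from_records(records)


def global_kd_effect(wt_response: pd.DataFrame) -> float:
    """Average fold change of the skipping:inclusion ratio under knockdown.

    ``exp`` of the mean, over wild-type minigenes and replicates, of
    ``ln R_2^KD - ln R_2^ctrl``.
    """
    return float(np.exp(wt_response["d_log_skip_vs_incl"].mean()))


def _ratio_isoforms(ratio: str):
    iso = ratio.removesuffix("_vs_incl")
    return "incl", iso


def call_synergistic(
    records: pd.DataFrame,
    ctrl_fit: EffectFit,
    fdr: float = 0.001,
    z_min: float = 2.0,
    excluded_positions=SPLICE_SITE_POSITIONS,
    min_ctrl_frequency: float = 0.01,
) -> pd.DataFrame:
    """Filter synergy records to significant, well-behaved calls.

    Drops mutations at the excluded (splice-site) positions and mutations
    whose predicted control frequency of either isoform in the tested ratio
    is below ``min_ctrl_frequency`` (splicing abolished on its own, so no
    further KD response is measurable).  Requires adjusted p < ``fdr``,
    |Stouffer z| > ``z_min`` and the same Delta sign in all replicates.
    Adds nested tier flags at |z| > 2 / 3 / 5.
    """
    rec = records.copy()
    rec = rec[~rec["position"].isin(set(excluded_positions))]
    rec = rec[(rec["p_adj"] < fdr)
              & (rec["z_stouffer"].abs() > z_min)
              & rec["direction_ok"]].copy()
    if rec.empty:
        for t in (2, 3, 5):
            rec[f"tier_gt{t}"] = pd.Series(dtype=bool)
        return rec.reset_index(drop=True)

    labels = sorted(rec["label"].unique())
    incidence = np.zeros((len(labels), len(ctrl_fit.labels)))
    for i, lab in enumerate(labels):
        incidence[i, ctrl_fit.index_of(lab)] = 1.0
    pred_ctrl = predict_frequencies_batch(ctrl_fit, incidence)
    pred = {lab: pred_ctrl[i] for i, lab in enumerate(labels)}

    def abolished(row):
        p = pred[row["label"]]
        return any(
            p[ISOFORMS.index(iso)] < min_ctrl_frequency
            for iso in _ratio_isoforms(row["ratio"])
        )

    rec = rec[~rec.apply(abolished, axis=1)].copy()
    for t in (2, 3, 5):
        rec[f"tier_gt{t}"] = rec["z_stouffer"].abs() > t
    return rec.reset_index(drop=True)
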
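"""Single-mutation effect inference by log-ratio least squares.

Each minigene variant carries several mutations, so its measured splicing
change is an overlay of effects.  Because mutation effects on isoform
*ratios* combine additively in log space (see :mod:`mutsplice.kinetics`),
the per-minigene log ratios obey a linear model

    ln(p_i / p_1)  =  alpha_i  +  sum_{m in minigene} beta_{m,i}

with one equation per minigene and one unknown beta per distinct mutation
and isoform ratio.  Solving the five systems (one per non-reference
isoform) in a least-squares sense deconvolves single-mutation effects from
combined measurements.  The wild-type intercept alpha_i is a free
parameter; the all-zero rows of the wild-type minigenes anchor it.

`MutationEffectRegressor` is the sklearn-style linear model at the centre;
`fit_effects`, `crossvalidate`, `leave_out_error_curve` and
`median_baseline` are the screen-level drivers built on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import lsqr
from sklearn.base import BaseEstimator, RegressorMixin

from .kinetics import ISOFORMS, ratios_to_frequencies
from .quantify import floored_log_ratios

__all__ = [
    "DesignMatrix",
    "build_design_matrix",
    "MutationEffectRegressor",
    "EffectFit",
    "fit_effects",
    "predict_frequencies",
    "crossvalidate",
    "leave_out_error_curve",
    "median_baseline",
]

RATIO_COLS = [f"log_ratio_{iso}" for iso in ISOFORMS[1:]]


@dataclass
class DesignMatrix:
    """Binary minigene x mutation incidence matrix.

    Columns are distinct mutation labels in lexicographic order; wild-type
    minigenes are all-zero rows.  ``occurrence`` holds column sums.
    """

    X: sparse.csr_matrix
    labels: list
    barcodes: list
    occurrence: np.ndarray

    @property
    def shape(self):
        return self.X.shape

    def rows_for(self, barcodes) -> np.ndarray:
        index = {b: i for i, b in enumerate(self.barcodes)}
        return np.array([index[b] for b in barcodes], dtype=int)


def build_design_matrix(library) -> DesignMatrix:
    labels = sorted({lab for v in library for lab in v.labels})
    col = {lab: j for j, lab in enumerate(labels)}
    rows, cols = [], []
    for i, v in enumerate(library):
        for lab in v.labels:
            rows.append(i)
            cols.append(col[lab])
    X = sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(library), len(labels))
    )
    return DesignMatrix(
        X=X,
        labels=labels,
        barcodes=[v.barcode for v in library],
        occurrence=np.asarray(X.sum(axis=0)).ravel(),
    )


class MutationEffectRegressor(BaseEstimator, RegressorMixin):
    """Sparse least-squares linear model with a free intercept.

    Solves ``min || y - intercept - X beta ||^2`` per target column with a
    deterministic iterative sparse solver (LSQR, tolerance 1e-10).  Columns
    that are exact duplicates of another column are perfectly confounded:
    their individual coefficients are not identifiable and are flagged in
    ``identifiable_mask_`` (LSQR returns the minimum-norm split between
    them).

    Attributes
    ----------
    coef_ : ndarray of shape (n_features, n_targets)
    intercept_ : ndarray of shape (n_targets,)
    identifiable_mask_ : bool ndarray of shape (n_features,)
    """

    def __init__(self, tol: float = 1e-10, max_iter: int = 20000,
                 fit_intercept: bool = True):
        self.tol = tol
        self.max_iter = max_iter
        self.fit_intercept = fit_intercept

    def fit(self, X, y):
        X = sparse.csr_matrix(X)
        y = np.asarray(y, dtype=float)
        squeeze = y.ndim == 1
        Y = y[:, None] if squeeze else y
        if X.shape[0] != Y.shape[0]:
            raise ValueError("X and y have incompatible shapes")
        if self.fit_intercept:
            A = sparse.hstack([np.ones((X.shape[0], 1)), X], format="csr")
        else:
            A = X
        coefs = np.empty((A.shape[1], Y.shape[1]))
        for j in range(Y.shape[1]):
            sol = lsqr(A, Y[:, j], atol=self.tol, btol=self.tol,
                       iter_lim=self.max_iter)
            coefs[:, j] = sol[0]
        if self.fit_intercept:
            self.intercept_ = coefs[0]
            self.coef_ = coefs[1:]
        else:
            self.intercept_ = np.zeros(Y.shape[1])
            self.coef_ = coefs
        self.identifiable_mask_ = ~_duplicate_columns(X)
        if squeeze:
            self.coef_ = self.coef_[:, 0]
            self.intercept_ = float(self.intercept_[0])
        return self

    def predict(self, X):
        X = sparse.csr_matrix(X)
        return self.intercept_ + X @ self.coef_


def _duplicate_columns(X: sparse.csr_matrix) -> np.ndarray:
    """Mark columns that coincide exactly with another column."""
    Xc = X.tocsc()
    seen: dict = {}
    dup = np.zeros(X.shape[1], dtype=bool)
    for j in range(X.shape[1]):
        key = (tuple(Xc.indices[Xc.indptr[j]:Xc.indptr[j + 1]]),
               tuple(Xc.data[Xc.indptr[j]:Xc.indptr[j + 1]]))
        if key in seen:
            dup[j] = True
            dup[seen[key]] = True
        else:
            seen[key] = j
    return dup


@dataclass
class EffectFit:
    """Fitted single-mutation effects on the five isoform ratios.

    ``beta`` is the replicate-averaged (n_labels, 5) matrix of natural-log
    fold changes on R_2..R_6; ``alpha`` the wild-type log ratios.
    Per-replicate estimates and presence masks are retained for the
    z-score and synergy workflows.
    """

    labels: list
    occurrence: np.ndarray
    beta: np.ndarray
    alpha: np.ndarray
    beta_reps: np.ndarray       # (R, n_labels, 5)
    alpha_reps: np.ndarray      # (R, 5)
    present_all: np.ndarray     # present in every replicate
    identifiable: np.ndarray
    replicates: list = field(default_factory=list)

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown mutation label: {label}") from None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"label": self.labels, "occurrence": self.occurrence})
        for i, iso in enumerate(ISOFORMS[1:]):
            df[f"beta_{iso}"] = self.beta[:, i]
            df[f"beta_{iso}_log2"] = self.beta[:, i] / np.log(2.0)
        pred = predict_frequencies_batch(self, np.eye(len(self.labels), dtype=bool))
        for i, iso in enumerate(ISOFORMS):
            df[f"pred_{iso}"] = pred[:, i]
        df["present_all_replicates"] = self.present_all
        df["identifiable"] = self.identifiable
        return df


def _log_ratio_matrix(freqs: pd.DataFrame) -> np.ndarray:
    return floored_log_ratios(freqs)[RATIO_COLS].to_numpy()


def fit_effects(library, freqs: pd.DataFrame, estimator=None) -> EffectFit:
    """Fit single-mutation ratio effects per replicate and average.

    ``freqs`` is the output of :func:`mutsplice.quantify.compute_frequencies`
    (one row per minigene x replicate, with ``total_pairs``).  Each
    replicate is fitted independently; betas are averaged across
    replicates.  Variants whose every carrier minigene was dropped in some
    replicate are flagged as not present in all replicates.
    """
    dm = build_design_matrix(library)
    reps = sorted(freqs["replicate"].unique())
    n_lab = len(dm.labels)
    beta_reps = np.full((len(reps), n_lab, 5), np.nan)
    alpha_reps = np.full((len(reps), 5), np.nan)
    present = np.ones((len(reps), n_lab), dtype=bool)
    est = estimator or MutationEffectRegressor()
    for r, rep in enumerate(reps):
        sub = freqs[freqs["replicate"] == rep]
        rows = dm.rows_for(sub["barcode"])
        Xr = dm.X[rows]
        Yr = _log_ratio_matrix(sub)
        est.fit(Xr, Yr)
        beta_reps[r] = est.coef_
        alpha_reps[r] = est.intercept_
        present[r] = np.asarray(Xr.sum(axis=0)).ravel() > 0
    present_all = present.all(axis=0)
    return EffectFit(
        labels=dm.labels,
        occurrence=dm.occurrence,
        beta=beta_reps.mean(axis=0),
        alpha=alpha_reps.mean(axis=0),
        beta_reps=beta_reps,
        alpha_reps=alpha_reps,
        present_all=present_all,
        identifiable=est.identifiable_mask_,
        replicates=list(reps),
    )


def predict_frequencies(fit: EffectFit, variant_labels, replicate=None) -> np.ndarray:
    """Predicted isoform frequencies for a set of mutations.

    ``exp(alpha_i + sum beta)`` gives the ratios R_2..R_6; frequencies
    follow from the normalisation p_1 = 1 / (1 + sum R).  An empty label
    set returns the fitted wild-type frequencies.
    """
    if replicate is None:
        alpha, beta = fit.alpha, fit.beta
    else:
        r = fit.replicates.index(replicate)
        alpha, beta = fit.alpha_reps[r], fit.beta_reps[r]
    log_r = alpha.copy()
    for lab in variant_labels:
        log_r = log_r + beta[fit.index_of(lab)]
    return ratios_to_frequencies(np.exp(log_r))


def predict_frequencies_batch(fit: EffectFit, incidence, replicate=None) -> np.ndarray:
    """Vectorised :func:`predict_frequencies` over an incidence matrix."""
    if replicate is None:
        alpha, beta = fit.alpha, fit.beta
    else:
        r = fit.replicates.index(replicate)
        alpha, beta = fit.alpha_reps[r], fit.beta_reps[r]
    log_r = alpha + np.asarray(incidence @ beta)
    return ratios_to_frequencies(np.exp(log_r))


def crossvalidate(library, freqs: pd.DataFrame, k: int = 10, seed: int = 0):
    """k-fold cross-validated prediction of held-out minigene frequencies.

    Returns ``(r_per_isoform, n_skipped_variants)`` where ``r_per_isoform``
    maps isoform name to the Pearson correlation between predicted and
    observed (replicate-mean) frequencies over all held-out minigenes.
    Variants unseen in a training fold are skipped in prediction and
    counted.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    rng = np.random.default_rng(seed)
    assignment = rng.permutation(len(library)) % k
    obs_mean = (
        freqs.groupby("barcode")[list(ISOFORMS)].mean()
    )
    preds, obs = [], []
    n_skipped = 0
    for f in range(k):
        train = [v for v, a in zip(library, assignment) if a != f]
        test = [v for v, a in zip(library, assignment) if a == f]
        train_bc = {v.barcode for v in train}
        fit = fit_effects(train, freqs[freqs["barcode"].isin(train_bc)])
        known = set(fit.labels)
        for v in test:
            if v.barcode not in obs_mean.index:
                continue
            usable = [lab for lab in v.labels if lab in known]
            n_skipped += len(v.labels) - len(usable)
            preds.append(predict_frequencies(fit, usable))
            obs.append(obs_mean.loc[v.barcode].to_numpy())
    preds = np.array(preds)
    obs = np.array(obs)
    r = {
        iso: float(np.corrcoef(preds[:, i], obs[:, i])[0, 1])
        for i, iso in enumerate(ISOFORMS)
    }
    return r, n_skipped


def median_baseline(library, freqs: pd.DataFrame) -> pd.DataFrame:
    """Median isoform frequency across all minigenes carrying each mutation.

    The simple proxy for single-mutation effects: medians are taken
    independently per isoform over the replicate-mean frequencies of the
    carrier minigenes.
    """
    obs_mean = freqs.groupby("barcode")[list(ISOFORMS)].mean()
    carriers: dict = {}
    for v in library:
        if v.barcode not in obs_mean.index:
            continue
        for lab in v.labels:
            carriers.setdefault(lab, []).append(v.barcode)
    rows = []
    for lab in sorted(carriers):
        block = obs_mean.loc[carriers[lab]]
        rows.append((lab, len(block), *block.median(axis=0).to_numpy()))
    return pd.DataFrame(rows, columns=["label", "occurrence", *ISOFORMS])


def leave_out_error_curve(
    library,
    freqs: pd.DataFrame,
    isoform: str = "incl",
    occurrences=(1, 2, 4, 8),
    max_mutations: int | None = 40,
    seed: int = 0,
    truth=None,
    wt_rates=None,
) -> pd.DataFrame:
    """Inference error versus mutation occurrence, with the 1/sqrt(n) overlay.

    For each mutation that the library contains as a single-mutation
    minigene, that minigene is held out, further carrier minigenes are
    removed successively so the effective occurrence runs over
    ``occurrences``, the model is refitted, and the error is the difference
    between the model-predicted frequency of ``isoform`` and the reference
    value for that single mutation.  The SD over mutations is reported per
    occurrence, for the regression and for the median baseline, together
    with the theoretical ``E ~ 1/sqrt(n)`` curve scaled at the largest
    occurrence.

    On real data the reference is the held-out minigene's observed
    frequency, so the curve carries that measurement's noise as a constant
    floor.  On synthetic data, passing the generator's ``truth`` (and
    optionally ``wt_rates``) replaces the reference by the noise-free
    expected frequency, isolating the inference error itself.

    Mutations lacking a single-mutation minigene are skipped; at most
    ``max_mutations`` are evaluated (drawn deterministically under
    ``seed``).
    """
    iso_idx = ISOFORMS.index(isoform)
    rng = np.random.default_rng(seed)
    obs_mean = freqs.groupby("barcode")[list(ISOFORMS)].mean()

    by_label: dict = {}
    singles: dict = {}
    for i, v in enumerate(library):
        for lab in v.labels:
            by_label.setdefault(lab, []).append(i)
        if len(v.mutations) == 1 and v.barcode in obs_mean.index:
            singles.setdefault(v.labels[0], i)

    max_occ = max(occurrences)
    eligible = sorted(
        lab for lab, idx in singles.items() if len(by_label[lab]) - 1 >= max_occ
    )
    if max_mutations is not None and len(eligible) > max_mutations:
        eligible = list(rng.choice(eligible, size=max_mutations, replace=False))

    # replicate-mean log ratios, one row per minigene, for fast refits
    dm = build_design_matrix(library)
    logr_mean = floored_log_ratios(freqs).groupby("barcode")[RATIO_COLS].mean()
    present = [b in logr_mean.index for b in dm.barcodes]
    base_rows = np.nonzero(present)[0]
    Y_full = logr_mean.loc[[dm.barcodes[i] for i in base_rows]].to_numpy()
    row_pos = {i: p for p, i in enumerate(base_rows)}

    errors: dict = {n: [] for n in occurrences}
    med_errors: dict = {n: [] for n in occurrences}
    est = MutationEffectRegressor()
    for lab in eligible:
        held = singles[lab]
        carriers = [i for i in by_label[lab] if i != held and i in row_pos]
        order = rng.permutation(len(carriers))
        if truth is not None:
            from .simulate import expected_frequencies, default_wt_rates

            reference = expected_frequencies(
                library[held], truth, wt_rates or default_wt_rates()
            )[iso_idx]
        else:
            reference = obs_mean.loc[library[held].barcode].to_numpy()[iso_idx]
        for n in occurrences:
            keep_carriers = {carriers[j] for j in order[:n]}
            drop = {held} | {c for c in carriers if c not in keep_carriers}
            rows = np.array([i for i in base_rows if i not in drop])
            Xs = dm.X[rows]
            Ys = Y_full[[row_pos[i] for i in rows]]
            est.fit(Xs, Ys)
            j = dm.labels.index(lab)
            log_r = est.intercept_ + est.coef_[j]
            p_pred = ratios_to_frequencies(np.exp(log_r))[iso_idx]
            errors[n].append(p_pred - reference)
            med = obs_mean.loc[
                [library[c].barcode for c in keep_carriers]
            ].to_numpy()[:, iso_idx]
            med_errors[n].append(np.median(med) - reference)

    occ = np.array(sorted(occurrences))
    sd_reg = np.array([np.std(errors[n], ddof=1) for n in occ])
    sd_med = np.array([np.std(med_errors[n], ddof=1) for n in occ])
    theory = sd_reg[-1] * np.sqrt(occ[-1] / occ)
    return pd.DataFrame(
        {"occurrence": occ, "sd_regression": sd_reg, "sd_median": sd_med,
         "theory_inv_sqrt": theory, "n_mutations": len(eligible)}
    )
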
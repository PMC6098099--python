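"""Synthetic minigene-library generator with known ground truth.

Emulates a random-mutagenesis splicing screen at the level the analysis
consumes: a library of barcoded minigene variants (~5200 mutated plus ~591
wild type), per-variant point mutations with a zero-truncated-Poisson load
(observed mean 3.6 mutations per mutated variant), planted per-mutation
log-effects on the five isoform ratios, a global knockdown shift on the
skipping:inclusion ratio with optional per-mutation synergy terms, and
read-pair counts drawn from a Dirichlet-multinomial whose overdispersion is
calibrated so the wild-type inclusion frequency scatters with ~3% SD.

Everything is deterministic under a seed, and the planted ground truth is
returned alongside the library so that every downstream inference stage has
a parameter-recovery test.

The measurement model is a deliberate simplification of targeted RNA-seq:
counts are exchangeable across read pairs, there are no PCR chimeras, no
barcode hopping, no position-dependent coverage, and no sequencing errors
except in the dedicated FASTQ fixtures.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .hill import HillParams, hill_curve
from .kinetics import ISOFORMS, SpliceRates, frequencies_to_ratios, ratios_to_frequencies

__all__ = [
    "MINIGENE_LENGTH",
    "Mutation",
    "MinigeneVariant",
    "GroundTruth",
    "DoseResponsePoint",
    "default_reference_sequence",
    "default_wt_rates",
    "generate_library",
    "simulate_counts",
    "calibrate_noise",
    "generate_dose_response",
]

#: Length of the minigene sense strand (nt).
MINIGENE_LENGTH = 707

_BASES = np.array(list("ACGT"))
_LABEL_RE = re.compile(r"^([ACGT])(\d+)([ACGT])$")


@dataclass(frozen=True)
class Mutation:
    """A point mutation on the minigene sense strand, e.g. ``G305A``."""

    position: int  # 1-based
    ref_base: str
    alt_base: str

    def __post_init__(self) -> None:
        if not 1 <= self.position <= MINIGENE_LENGTH:
            raise ValueError(f"position {self.position} outside minigene")
        if self.ref_base == self.alt_base:
            raise ValueError("ref and alt base must differ")

    @property
    def label(self) -> str:
        return f"{self.ref_base}{self.position}{self.alt_base}"

    @classmethod
    def from_label(cls, label: str) -> "Mutation":
        m = _LABEL_RE.match(label)
        if not m:
            raise ValueError(f"unparseable mutation label: {label!r}")
        return cls(position=int(m.group(2)), ref_base=m.group(1), alt_base=m.group(3))


@dataclass(frozen=True)
class MinigeneVariant:
    """One barcoded reporter: 15-nt barcode plus its mutation list."""

    barcode: str
    mutations: tuple = ()

    def __post_init__(self) -> None:
        if len(self.barcode) != 15:
            raise ValueError("barcode must be 15 nt")

    @property
    def is_wt(self) -> bool:
        return len(self.mutations) == 0

    @property
    def labels(self) -> tuple:
        return tuple(m.label for m in self.mutations)


@dataclass
class GroundTruth:
    """Planted per-mutation effects consumed by recovery tests.

    ``effect`` maps a mutation label to the 5-vector of natural-log fold
    changes on the ratios R_2..R_6 (skip, ir_full, ir_first, ir_second,
    other — each relative to inclusion).  ``kd_global`` is the log fold
    change applied to R_2 for every minigene under knockdown; ``synergy``
    holds per-mutation extra log fold changes on R_2 applied only under
    knockdown.
    """

    effect: dict = field(default_factory=dict)
    kd_global: float = 0.0
    synergy: dict = field(default_factory=dict)


@dataclass(frozen=True)
class DoseResponsePoint:
    """One dose point: relative protein level x, deltaPSI y, SD sigma."""

    x: float
    y: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


def default_reference_sequence(length: int = MINIGENE_LENGTH) -> str:
    """Deterministic synthetic minigene reference sequence.

    A fixed-seed random sequence standing in for a real reporter construct
    (the generator only needs consistent ref bases and some G-runs, which
    arise naturally in random sequence).
    """
    rng = np.random.default_rng(707)
    return "".join(rng.choice(_BASES, size=length))


#: Wild-type frequencies used by default: mostly exon inclusion, ~10%
#: skipping, small intron-retention and non-canonical fractions.
DEFAULT_WT_FREQUENCIES = np.array([0.80, 0.10, 0.05, 0.02, 0.02, 0.01])


def default_wt_rates() -> SpliceRates:
    """Rates whose steady state reproduces :data:`DEFAULT_WT_FREQUENCIES`."""
    # scale chosen so the pooled K_3 = 25 * 0.05 = 1.25 >= 1
    return SpliceRates.from_K(25.0 * DEFAULT_WT_FREQUENCIES)


def _zt_poisson_lambda(mean: float) -> float:
    """Rate of a zero-truncated Poisson with the given truncated mean."""
    if mean <= 1.0:
        raise ValueError("truncated mean must exceed 1")
    return brentq(lambda lam: lam / (1.0 - np.exp(-lam)) - mean, 1e-9, 10 * mean)


def _sample_zt_poisson(rng, lam: float, size: int) -> np.ndarray:
    counts = rng.poisson(lam, size=size)
    zero = counts == 0
    while zero.any():
        counts[zero] = rng.poisson(lam, size=int(zero.sum()))
        zero = counts == 0
    return counts


def generate_library(
    n_mutated: int = 5200,
    n_wt: int = 591,
    mean_mutations: float = 3.6,
    seed: int | None = None,
    *,
    reference: str | None = None,
    effect_fraction: float = 0.4,
    effect_sd: float = 1.2,
    kd_global: float = 0.0,
    synergy_fraction: float = 0.0,
    synergy_sd: float = 0.6,
    max_barcode_retries: int = 100,
):
    """Generate a barcoded minigene library and its planted ground truth.

    Mutation counts per mutated variant follow a zero-truncated Poisson
    whose *mean equals* ``mean_mutations``; positions are uniform over the
    minigene, alternative bases uniform over the three non-reference bases.
    A fraction ``effect_fraction`` of distinct mutations receives a
    non-zero effect: an i.i.d. Gaussian(0, ``effect_sd``) log fold change on
    each isoform ratio; the rest are exactly neutral.  With
    ``synergy_fraction > 0``, that fraction of effectful mutations also
    receives a Gaussian(0, ``synergy_sd``) knockdown-only term on R_2.

    Returns ``(variants, truth)``.
    """
    if n_mutated <= 0 or n_wt <= 0:
        raise ValueError("n_mutated and n_wt must be positive")
    rng = np.random.default_rng(seed)
    reference = reference or default_reference_sequence()

    lam = _zt_poisson_lambda(mean_mutations)
    counts = _sample_zt_poisson(rng, lam, n_mutated)

    barcodes = _unique_barcodes(rng, n_mutated + n_wt, max_barcode_retries)

    variants = []
    truth = GroundTruth(kd_global=kd_global)
    for i in range(n_mutated):
        positions = rng.choice(MINIGENE_LENGTH, size=counts[i], replace=False) + 1
        muts = []
        for pos in np.sort(positions):
            ref = reference[pos - 1]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            muts.append(Mutation(int(pos), ref, str(alt)))
        variants.append(MinigeneVariant(barcodes[i], tuple(muts)))
        for m in muts:
            if m.label not in truth.effect:
                if rng.uniform() < effect_fraction:
                    eff = rng.normal(0.0, effect_sd, size=5)
                    truth.effect[m.label] = eff
                    if synergy_fraction > 0 and rng.uniform() < synergy_fraction:
                        truth.synergy[m.label] = float(rng.normal(0.0, synergy_sd))
                else:
                    truth.effect[m.label] = np.zeros(5)
    for i in range(n_wt):
        variants.append(MinigeneVariant(barcodes[n_mutated + i]))
    return variants, truth


def _unique_barcodes(rng, n: int, max_retries: int) -> list:
    seen: set = set()
    out: list = []
    for _ in range(max_retries):
        need = n - len(out)
        if need == 0:
            break
        block = ["".join(bc) for bc in rng.choice(_BASES, size=(need, 15))]
        for bc in block:
            if bc not in seen:
                seen.add(bc)
                out.append(bc)
    if len(out) < n:
        raise RuntimeError("could not generate unique barcodes")
    return out


def expected_frequencies(
    variant: MinigeneVariant,
    truth: GroundTruth,
    wt_rates: SpliceRates,
    condition: str = "ctrl",
) -> np.ndarray:
    """Noise-free isoform frequencies implied by the planted ground truth."""
    log_r = np.log(frequencies_to_ratios(wt_rates.K / wt_rates.K.sum()))
    for lab in variant.labels:
        if lab not in truth.effect:
            raise KeyError(f"mutation {lab} missing from ground truth")
        log_r = log_r + truth.effect[lab]
    if condition == "kd":
        log_r[0] += truth.kd_global
        for lab in variant.labels:
            log_r[0] += truth.synergy.get(lab, 0.0)
    elif condition != "ctrl":
        raise ValueError("condition must be 'ctrl' or 'kd'")
    return ratios_to_frequencies(np.exp(log_r))


def simulate_counts(
    library,
    truth: GroundTruth,
    wt_rates: SpliceRates | None = None,
    depth: int = 1000,
    overdispersion: float = 0.0,
    n_replicates: int = 3,
    condition: str = "ctrl",
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate per-minigene isoform read-pair counts.

    Counts per (minigene, replicate) are Dirichlet-multinomial around the
    ground-truth expected frequencies.  ``overdispersion`` is the excess
    variance parameter rho >= 0: the Dirichlet concentration is 1/rho, and
    rho = 0 reduces exactly to multinomial sampling.  Replicates use
    independent streams spawned from the master seed.
    """
    if depth < 100:
        raise ValueError("depth must be at least 100")
    if overdispersion < 0:
        raise ValueError("overdispersion must be non-negative")
    wt_rates = wt_rates or default_wt_rates()
    missing = sorted(
        {lab for v in library for lab in v.labels if lab not in truth.effect}
    )
    if missing:
        raise KeyError(f"mutations missing from ground truth: {missing}")

    P = np.stack([expected_frequencies(v, truth, wt_rates, condition) for v in library])
    ss = np.random.SeedSequence(seed)
    rows = []
    for rep, child in enumerate(ss.spawn(n_replicates), start=1):
        rng = np.random.default_rng(child)
        if overdispersion > 0:
            conc = P / overdispersion
            gam = rng.gamma(np.clip(conc, 1e-12, None))
            probs = gam / gam.sum(axis=1, keepdims=True)
        else:
            probs = P
        counts = rng.multinomial(depth, probs)
        for v, row in zip(library, counts):
            rows.append((v.barcode, rep, condition, *row))
    return pd.DataFrame(rows, columns=["barcode", "replicate", "condition", *ISOFORMS])


def calibrate_noise(
    target_wt_sd: float = 0.03,
    depth: int = 1000,
    wt_rates: SpliceRates | None = None,
    n_sim: int = 2000,
    seed: int = 0,
    rel_tol: float = 0.02,
    max_iter: int = 40,
) -> float:
    """Overdispersion rho such that simulated wt inclusion SD hits the target.

    Bisects rho against direct simulation of ``n_sim`` wild-type minigenes
    at the given depth.  Raises if the target is below the multinomial
    sampling floor at this depth.
    """
    wt_rates = wt_rates or default_wt_rates()
    p_wt = wt_rates.K / wt_rates.K.sum()

    def wt_sd(rho: float, salt: int) -> float:
        rng = np.random.default_rng(np.random.SeedSequence((seed, salt)))
        if rho > 0:
            gam = rng.gamma(np.tile(p_wt / rho, (n_sim, 1)))
            probs = gam / gam.sum(axis=1, keepdims=True)
        else:
            probs = np.tile(p_wt, (n_sim, 1))
        counts = rng.multinomial(depth, probs)
        return float(np.std(counts[:, 0] / depth, ddof=1))

    floor = wt_sd(0.0, 0)
    if floor >= target_wt_sd:
        raise ValueError(
            f"target SD {target_wt_sd} unreachable: multinomial floor at depth "
            f"{depth} is {floor:.4f}"
        )
    lo, hi = 0.0, 1e-3
    it = 0
    while wt_sd(hi, 1) < target_wt_sd:
        hi *= 2.0
        it += 1
        if it > 30:
            raise RuntimeError("failed to bracket the target overdispersion")
    for it in range(max_iter):
        mid = 0.5 * (lo + hi)
        s = wt_sd(mid, 2 + it)
        if abs(s - target_wt_sd) <= rel_tol * target_wt_sd:
            return mid
        if s < target_wt_sd:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_dose_response(
    params: HillParams,
    x_grid,
    sigma: float,
    seed: int | None = None,
) -> list:
    """Dose-response points on a Hill curve with Gaussian measurement noise."""
    x_grid = np.asarray(x_grid, dtype=float)
    if np.any(x_grid <= 0):
        raise ValueError("protein levels must be positive")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    y = hill_curve(x_grid, params) + rng.normal(0.0, sigma, size=x_grid.shape)
    recorded = sigma if sigma > 0 else 1e-6
    return [DoseResponsePoint(float(x), float(v), recorded) for x, v in zip(x_grid, y)]


# ---------------------------------------------------------------------------
# TSV / FASTA round trips


def library_to_frame(library) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "barcode": [v.barcode for v in library],
            "mutation_labels": [";".join(v.labels) for v in library],
            "is_wt": [v.is_wt for v in library],
        }
    )


def library_from_frame(df: pd.DataFrame) -> list:
    out = []
    for _, row in df.iterrows():
        labels = [s for s in str(row["mutation_labels"]).split(";") if s and s != "nan"]
        muts = tuple(Mutation.from_label(s) for s in labels)
        out.append(MinigeneVariant(row["barcode"], muts))
    return out


def write_library(library, path) -> None:
    library_to_frame(library).to_csv(path, sep="\t", index=False)


def read_library(path) -> list:
    return library_from_frame(pd.read_csv(path, sep="\t", keep_default_na=False))


def truth_to_frame(truth: GroundTruth) -> pd.DataFrame:
    rows = []
    for lab, eff in truth.effect.items():
        rows.append((lab, *eff, truth.synergy.get(lab, 0.0)))
    cols = ["label"] + [f"log_effect_{iso}" for iso in ISOFORMS[1:]] + ["synergy"]
    df = pd.DataFrame(rows, columns=cols)
    df.attrs["kd_global"] = truth.kd_global
    return df


def truth_from_frame(df: pd.DataFrame, kd_global: float = 0.0) -> GroundTruth:
    truth = GroundTruth(kd_global=df.attrs.get("kd_global", kd_global))
    eff_cols = [f"log_effect_{iso}" for iso in ISOFORMS[1:]]
    for _, row in df.iterrows():
        truth.effect[row["label"]] = row[eff_cols].to_numpy(dtype=float)
        if row.get("synergy", 0.0):
            truth.synergy[row["label"]] = float(row["synergy"])
    return truth


def write_reference_fasta(path, sequence: str | None = None, name: str = "minigene") -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    rec = SeqRecord(Seq(sequence or default_reference_sequence()), id=name, description="")
    SeqIO.write([rec], path, "fasta")


def read_reference_fasta(path) -> str:
    from Bio import SeqIO

    rec = next(SeqIO.parse(path, "fasta"))
    return str(rec.seq)
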
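"""Kinetic model of a five-isoform splicing decision.

A pre-mRNA precursor ``x0`` is transcribed at constant rate ``c`` and
converted with linear kinetics into five canonical splice products
(alternative-exon inclusion, skipping, full/first/second intron retention)
plus one pooled non-canonical species, with production rates ``r_i`` and
first-order degradation rates ``d_i``:

    dx0/dt = c - (r1 + ... + r6) * x0
    dxi/dt = r_i * x0 - d_i * x_i        (i = 1..6)

At steady state the measurable isoform frequencies depend on the rates only
through the effective splice rates ``K_j = r_j / d_j`` (``j != 3``) and
``K_3 = 1 + r_3 / d_3`` — the full-intron-retention isoform is pooled with
the unspliced precursor, which sequencing cannot distinguish from it:

    p_i = K_i / (K_1 + K_2 + K_3 + K_4 + K_5 + K_6)

The decisive consequence for inference is that isoform *ratios* relative to
inclusion, ``R_i = p_i / p_1 = K_i / K_1``, respond multiplicatively and
hence log-additively to mutations that rescale individual ``K_i`` — whereas
frequencies ``p_i`` do not, because of the shared normalisation.  All
downstream regression in :mod:`mutsplice.inference` rests on this identity.

Natural logarithms are used for all effect arithmetic; exported tables add a
log2 column for readability.  Time units are arbitrary: only steady-state
ratios matter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

#: Canonical isoform order used throughout the package.
ISOFORMS = ("incl", "skip", "ir_full", "ir_first", "ir_second", "other")
N_ISOFORMS = 6

__all__ = [
    "ISOFORMS",
    "N_ISOFORMS",
    "SpliceRates",
    "DegenerateRatesError",
    "steady_state_frequencies",
    "integrate_ode",
    "apply_mutation_effects",
    "frequencies_to_ratios",
    "ratios_to_frequencies",
]


class DegenerateRatesError(ValueError):
    """All effective splice rates are zero — no isoform is produced."""


class InclusionAbolishedError(ValueError):
    """Inclusion frequency is zero; ratios relative to inclusion diverge.

    Callers quantifying real counts should apply the depth-aware floor
    policy (see :func:`mutsplice.quantify.compute_frequencies`) before
    forming ratios.
    """


@dataclass(frozen=True)
class SpliceRates:
    """Rate constants of the splicing reaction network.

    Parameters
    ----------
    c : float
        Pre-mRNA production rate (concentration / time).
    r : array-like of 6 floats
        Production rates ``r_1..r_6`` (1 / time) for inclusion, skipping,
        full/first/second intron retention and the pooled non-canonical
        isoform.
    d : array-like of 6 floats
        Degradation rates ``d_1..d_6`` (1 / time); all strictly positive.
    """

    c: float
    r: np.ndarray
    d: np.ndarray = field(default_factory=lambda: np.ones(N_ISOFORMS))

    def __post_init__(self) -> None:
        object.__setattr__(self, "r", np.asarray(self.r, dtype=float))
        object.__setattr__(self, "d", np.asarray(self.d, dtype=float))
        if self.r.shape != (N_ISOFORMS,) or self.d.shape != (N_ISOFORMS,):
            raise ValueError("r and d must each have 6 entries")
        if self.c < 0 or np.any(self.r < 0):
            raise ValueError("production rates must be non-negative")
        if np.any(self.d <= 0):
            raise ValueError("degradation rates must be strictly positive")

    @property
    def K(self) -> np.ndarray:
        """Effective splice rates; ``K_3`` pools precursor and full IR."""
        K = self.r / self.d
        K[2] += 1.0
        return K

    @classmethod
    def from_K(cls, K, c: float = 1.0) -> "SpliceRates":
        """Construct rates with unit degradation realising the given ``K``.

        Requires ``K_3 >= 1`` (the pooled species always contains at least
        the unspliced precursor).
        """
        K = np.asarray(K, dtype=float)
        if K.shape != (N_ISOFORMS,):
            raise ValueError("K must have 6 entries")
        if K[2] < 1.0:
            raise ValueError("K_3 < 1 is unrealisable: it pools the precursor")
        r = K.copy()
        r[2] = K[2] - 1.0
        return cls(c=c, r=r)


def steady_state_frequencies(rates: SpliceRates) -> np.ndarray:
    """Steady-state isoform frequencies ``p_i = K_i / sum_j K_j``.

    Raises
    ------
    DegenerateRatesError
        If every effective rate is zero.
    """
    K = rates.K
    total = K.sum()
    if total <= 0:
        raise DegenerateRatesError("all effective splice rates are zero")
    return K / total


def integrate_ode(
    rates: SpliceRates,
    t_end: float,
    x0: np.ndarray | None = None,
    n_points: int = 50,
):
    """Integrate the reaction ODEs from ``x0`` to ``t_end``.

    Returns ``(t, X)`` where ``X`` has shape ``(len(t), 7)`` with columns
    ``x0, x1..x6``.  At large ``t_end`` the normalised abundances (pooling
    the precursor into isoform 3) converge to
    :func:`steady_state_frequencies`.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if x0 is None:
        x0 = np.zeros(N_ISOFORMS + 1)
    x0 = np.asarray(x0, dtype=float)
    if x0.shape != (N_ISOFORMS + 1,) or np.any(x0 < 0):
        raise ValueError("initial state must be 7 non-negative concentrations")

    r, d, c = rates.r, rates.d, rates.c
    r_total = r.sum()

    def rhs(_t, x):
        dx = np.empty_like(x)
        dx[0] = c - r_total * x[0]
        dx[1:] = r * x[0] - d * x[1:]
        return dx

    t_eval = np.linspace(0.0, t_end, n_points)
    sol = solve_ivp(rhs, (0.0, t_end), x0, method="LSODA", t_eval=t_eval,
                    rtol=1e-10, atol=1e-12)
    if not sol.success:  # pragma: no cover - LSODA handles this linear system
        raise RuntimeError(
            f"ODE integration failed ({sol.message}) for rates c={c}, r={r}, d={d}"
        )
    return sol.t, sol.y.T


def ode_steady_frequencies(rates: SpliceRates, t_end: float = 1e4) -> np.ndarray:
    """Isoform frequencies from long-time ODE integration (simulation oracle).

    The precursor ``x0`` is pooled into isoform 3, mirroring what the
    sequencing assay measures.
    """
    _, X = integrate_ode(rates, t_end=t_end, n_points=2)
    x = X[-1]
    pooled = x[1:].copy()
    pooled[2] += x[0]
    return pooled / pooled.sum()


def apply_mutation_effects(base: SpliceRates, effects) -> SpliceRates:
    """Apply multiplicative mutation effects to the effective splice rates.

    Each element of ``effects`` is a 6-vector of natural-log fold changes on
    ``K_1..K_6``; combined effects multiply, i.e.
    ``K_i(out) = K_i(base) * exp(sum_m effect[m, i])``.  Order of application
    is irrelevant.
    """
    effects = np.atleast_2d(np.asarray(effects, dtype=float)) if len(effects) else np.zeros((0, N_ISOFORMS))
    if effects.size and effects.shape[1] != N_ISOFORMS:
        raise ValueError("each effect must give a log fold change per isoform")
    if not np.all(np.isfinite(effects)):
        raise ValueError("mutation effects must be finite")
    K = base.K * np.exp(effects.sum(axis=0))
    return SpliceRates.from_K(K, c=base.c)


def frequencies_to_ratios(p) -> np.ndarray:
    """Isoform ratios ``R_i = p_i / p_1`` for i = 2..6 (``R_1 = 1`` implicit)."""
    p = np.asarray(p, dtype=float)
    if np.any(p[..., 0] <= 0):
        raise InclusionAbolishedError("p_1 = 0: ratios relative to inclusion undefined")
    return p[..., 1:] / p[..., :1]


def ratios_to_frequencies(R) -> np.ndarray:
    """Inverse of :func:`frequencies_to_ratios`.

    ``p_1 = 1 / (1 + sum R)``, ``p_i = R_i * p_1``.  Works on batches: the
    last axis holds the 5 ratios.
    """
    R = np.asarray(R, dtype=float)
    if np.any(R < 0) or not np.all(np.isfinite(R)):
        raise ValueError("ratios must be finite and non-negative")
    p1 = 1.0 / (1.0 + R.sum(axis=-1, keepdims=True))
    return np.concatenate([p1, R * p1], axis=-1)


def rates_to_frame(rates: SpliceRates):
    """Tabulate effective rates and steady-state frequencies per isoform."""
    import pandas as pd

    return pd.DataFrame({"isoform": ISOFORMS, "K": rates.K,
                         "p": steady_state_frequencies(rates)})


def write_rates(rates: SpliceRates, path) -> None:
    rates_to_frame(rates).to_csv(path, sep="\t", index=False)
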
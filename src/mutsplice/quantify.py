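"""Barcode extraction, isoform frequency computation and read filters.

Implements the screen's data-reduction rules: the 15-nt barcode on read #1
is located between the flanking restriction sites TCTAGA and GGATCC (one
mismatch allowed in each flank) and accepted only if every barcode base has
Phred >= 30; per-minigene isoform counts are cleaned by zeroing isoforms
supported by <1% of read pairs or by fewer than two read pairs, minigenes
with fewer than 100 remaining read pairs are dropped; DNA-seq variant calls
are retained when Alt/(Alt+Ref) > 0.8 and (Alt+Ref)/total > 0.5.

Boundary semantics are strict readings of those rules: exactly 1% support or
exactly two read pairs is retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinetics import ISOFORMS

__all__ = [
    "BarcodeResult",
    "extract_barcode",
    "extract_barcodes_fastq",
    "compute_frequencies",
    "floored_log_ratios",
    "filter_variant_calls",
]

LEFT_FLANK = "TCTAGA"
RIGHT_FLANK = "GGATCC"
BARCODE_LEN = 15


@dataclass(frozen=True)
class BarcodeResult:
    barcode: str | None
    reason: str | None  # None on success; no_flank | ambiguous | low_quality

    @property
    def ok(self) -> bool:
        return self.barcode is not None


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def extract_barcode(seq: str, quals, min_phred: int = 30,
                    max_flank_mismatch: int = 1) -> BarcodeResult:
    """Extract the 15-nt barcode between the two flanking sites on read #1.

    Scans every placement where a left flank (TCTAGA) and a right flank
    (GGATCC) bound a 15-nt insert, each flank allowing up to one mismatch.
    Rejections are data, not errors: the reason code is ``no_flank`` (no
    valid placement), ``ambiguous`` (conflicting placements) or
    ``low_quality`` (a barcode base under the Phred threshold).
    """
    seq = seq.upper()
    L, R, B = len(LEFT_FLANK), len(RIGHT_FLANK), BARCODE_LEN
    hits = []
    for i in range(0, len(seq) - (L + B + R) + 1):
        if _mismatches(seq[i:i + L], LEFT_FLANK) <= max_flank_mismatch and \
           _mismatches(seq[i + L + B:i + L + B + R], RIGHT_FLANK) <= max_flank_mismatch:
            hits.append(i + L)
    if not hits:
        return BarcodeResult(None, "no_flank")
    barcodes = {seq[s:s + B] for s in hits}
    if len(barcodes) > 1:
        return BarcodeResult(None, "ambiguous")
    start = hits[0]
    q = np.asarray(quals)
    if np.any(q[start:start + B] < min_phred):
        return BarcodeResult(None, "low_quality")
    return BarcodeResult(seq[start:start + B], None)


def extract_barcodes_fastq(path, min_phred: int = 30) -> pd.DataFrame:
    """Run :func:`extract_barcode` over a FASTQ file of read #1 sequences.

    Returns a frame with columns ``read_id, barcode, reason``.
    """
    from Bio import SeqIO

    rows = []
    for rec in SeqIO.parse(str(path), "fastq"):
        res = extract_barcode(str(rec.seq), rec.letter_annotations["phred_quality"],
                              min_phred=min_phred)
        rows.append((rec.id, res.barcode if res.ok else "", res.reason or ""))
    return pd.DataFrame(rows, columns=["read_id", "barcode", "reason"])


def compute_frequencies(
    table: pd.DataFrame,
    min_pairs_per_minigene: int = 100,
    min_isoform_fraction: float = 0.01,
    min_isoform_pairs: int = 2,
    library_wide: bool = False,
):
    """Per-minigene isoform frequencies after the support/coverage filters.

    For each row (one minigene in one replicate and condition), isoform
    counts supported by strictly less than ``min_isoform_fraction`` of the
    row's read pairs, or by strictly fewer than ``min_isoform_pairs`` pairs,
    are zeroed; rows whose remaining total falls below
    ``min_pairs_per_minigene`` are dropped.  Frequencies are renormalised to
    sum to 1.

    With ``library_wide=True`` an isoform failing the support rule in any
    row is instead zeroed across the whole table (the alternative reading
    of the filtering rule).

    Returns ``(freqs, dropped)``: ``freqs`` has the input key columns plus
    one frequency column per isoform and ``total_pairs``; ``dropped`` lists
    removed rows with a reason.
    """
    counts = table[list(ISOFORMS)].to_numpy(dtype=float)
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        frac = np.divide(counts, totals, out=np.zeros_like(counts), where=totals > 0)
    fail = (frac < min_isoform_fraction) | (counts < min_isoform_pairs)
    if library_wide:
        fail = np.tile(fail.any(axis=0), (len(counts), 1))
    kept = np.where(fail, 0.0, counts)
    new_totals = kept.sum(axis=1)

    keep_row = new_totals >= min_pairs_per_minigene
    key_cols = [c for c in ("barcode", "replicate", "condition") if c in table.columns]
    dropped = table.loc[~keep_row, key_cols].copy()
    dropped["reason"] = np.where(new_totals[~keep_row] > 0, "low_coverage", "no_reads")

    freqs = table.loc[keep_row, key_cols].copy()
    surv = kept[keep_row]
    freqs[list(ISOFORMS)] = surv / surv.sum(axis=1, keepdims=True)
    freqs["total_pairs"] = new_totals[keep_row].astype(int)
    return freqs.reset_index(drop=True), dropped.reset_index(drop=True)


def floored_log_ratios(freqs: pd.DataFrame) -> pd.DataFrame:
    """Natural-log isoform ratios ln(p_i / p_1) with a depth-aware floor.

    Zero frequencies are floored at ``1 / (total_pairs + 1)`` before the
    ratio is formed, so the floor vanishes with coverage; the policy keeps
    inclusion-abolished minigenes usable in the regression.
    """
    p = freqs[list(ISOFORMS)].to_numpy(dtype=float)
    floor = 1.0 / (freqs["total_pairs"].to_numpy(dtype=float) + 1.0)
    p = np.maximum(p, floor[:, None])
    out = freqs.drop(columns=list(ISOFORMS)).copy()
    logr = np.log(p[:, 1:] / p[:, :1])
    out[[f"log_ratio_{iso}" for iso in ISOFORMS[1:]]] = logr
    return out


def filter_variant_calls(calls: pd.DataFrame,
                         min_penetrance: float = 0.8,
                         min_allele_coverage: float = 0.5) -> pd.DataFrame:
    """SNV penetrance filter on per-position allele counts.

    Keeps calls with ``alt / (alt + ref) > min_penetrance`` and
    ``(alt + ref) / total > min_allele_coverage`` (both strict).  Calls with
    ``alt + ref == 0`` are rejected, not raised.
    """
    alt = calls["alt_count"].to_numpy(dtype=float)
    ref = calls["ref_count"].to_numpy(dtype=float)
    total = calls["total_count"].to_numpy(dtype=float)
    ar = alt + ref
    with np.errstate(invalid="ignore", divide="ignore"):
        keep = (ar > 0) & (alt / np.where(ar > 0, ar, 1) > min_penetrance) \
            & (ar / np.where(total > 0, total, np.inf) > min_allele_coverage)
    return calls.loc[keep].reset_index(drop=True)
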
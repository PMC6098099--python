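"""Splice-regulatory binding-site (SRBS) annotation and G-run classification.

Candidate RBP motif sites (scanned externally against the minigene and
supplied as a table) are filtered to SRBS: sites in which at least 60% of
positions are splicing-effective for at least one isoform.  Overlapping
same-RBP sites (overlap >= 2 nt) are collapsed into their union interval
when the union still passes the 60% rule, otherwise kept unmerged.  Point
mutations are classified against the maximal G-runs of the reference
sequence: G-to-H inside a run disrupts it, H-to-G immediately adjacent
extends it.

Coordinates are 1-based inclusive on the minigene sense strand; helpers
convert to and from 0-based half-open BED.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

from .simulate import Mutation

__all__ = [
    "MotifSite",
    "GRun",
    "find_gruns",
    "effective_fraction",
    "filter_srbs",
    "collapse_srbs",
    "classify_grun_mutation",
    "sites_to_bed",
    "sites_from_bed",
]


@dataclass(frozen=True)
class MotifSite:
    """A candidate RBP binding site, 1-based inclusive coordinates."""

    rbp: str
    start: int
    end: int
    motif: str = ""

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError("require 1 <= start <= end")

    @property
    def positions(self) -> range:
        return range(self.start, self.end + 1)

    def overlap(self, other: "MotifSite") -> int:
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)


@dataclass(frozen=True)
class GRun:
    """A maximal run of >= min_len consecutive guanines."""

    start: int
    end: int


def find_gruns(sequence: str, min_len: int = 3) -> list:
    """Maximal runs of at least ``min_len`` consecutive G (1-based)."""
    return [
        GRun(m.start() + 1, m.end())
        for m in re.finditer(f"G{{{min_len},}}", sequence.upper())
    ]


def effective_fraction(site: MotifSite, effective_positions: dict) -> dict:
    """Fraction of site positions that are splicing-effective, per isoform."""
    n = site.end - site.start + 1
    return {
        iso: sum(1 for p in site.positions if p in posset) / n
        for iso, posset in effective_positions.items()
    }


def filter_srbs(sites, effective_positions: dict, minigene_length: int = 707,
                min_fraction: float = 0.60) -> list:
    """Retain sites with >= 60% splicing-effective positions for >= 1 isoform.

    Duplicate site records (same RBP and interval) are removed first.
    ``effective_positions`` maps isoform name to a set of effective
    positions.
    """
    seen = set()
    unique = []
    for s in sites:
        if s.end > minigene_length:
            raise ValueError(f"site {s} extends beyond the minigene")
        key = (s.rbp, s.start, s.end)
        if key not in seen:
            seen.add(key)
            unique.append(s)
    return [
        s for s in unique
        if max(effective_fraction(s, effective_positions).values(), default=0.0)
        >= min_fraction
    ]


def collapse_srbs(sites, effective_positions: dict,
                  min_overlap: int = 2, min_fraction: float = 0.60) -> list:
    """Collapse overlapping same-RBP SRBS to a fixed point.

    Two sites of the same RBP overlapping by at least ``min_overlap`` nt are
    merged into their union interval if the union still passes the
    ``min_fraction`` rule for at least one isoform; otherwise both are kept
    unmerged.  Merging iterates until no further merge applies.
    """
    def passes(s: MotifSite) -> bool:
        return max(effective_fraction(s, effective_positions).values(),
                   default=0.0) >= min_fraction

    out = []
    for rbp in sorted({s.rbp for s in sites}):
        group = sorted((s for s in sites if s.rbp == rbp),
                       key=lambda s: (s.start, s.end))
        changed = True
        while changed:
            changed = False
            merged = []
            i = 0
            while i < len(group):
                s = group[i]
                if i + 1 < len(group):
                    t = group[i + 1]
                    if s.overlap(t) >= min_overlap:
                        union = MotifSite(rbp, min(s.start, t.start),
                                          max(s.end, t.end))
                        if passes(union):
                            merged.append(union)
                            i += 2
                            changed = True
                            continue
                merged.append(s)
                i += 1
            group = sorted(merged, key=lambda s: (s.start, s.end))
        out.extend(group)
    return out


def classify_grun_mutation(mutation: Mutation, gruns) -> str:
    """Classify a point mutation as G-run ``disrupting``, ``extending`` or
    ``neither``.

    Disrupting: a G-to-H change (H = A/C/T) at any position inside a G-run.
    Extending: an H-to-G change at a position immediately flanking a run.
    """
    pos = mutation.position
    if mutation.ref_base == "G" and mutation.alt_base in "ACT":
        if any(g.start <= pos <= g.end for g in gruns):
            return "disrupting"
    if mutation.ref_base in "ACT" and mutation.alt_base == "G":
        if any(pos == g.start - 1 or pos == g.end + 1 for g in gruns):
            return "extending"
    return "neither"


def sites_to_bed(sites, chrom: str = "minigene") -> pd.DataFrame:
    """Convert 1-based inclusive sites to 0-based half-open BED records."""
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": [s.start - 1 for s in sites],
            "end": [s.end for s in sites],
            "name": [s.rbp for s in sites],
        }
    )


def sites_from_bed(bed: pd.DataFrame) -> list:
    """Inverse of :func:`sites_to_bed`."""
    return [
        MotifSite(rbp=row["name"], start=int(row["start"]) + 1, end=int(row["end"]))
        for _, row in bed.iterrows()
    ]
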
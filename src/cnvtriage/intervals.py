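"""Genomic interval algebra on 1-based, fully-closed coordinates.

Every filter in the pipeline reduces to one of four primitive questions
about a pair of intervals: do they overlap, does one contain the other,
how many bases do they share, and what fraction of each is shared.
Coordinates are kept 1-based inclusive throughout the package, matching
the ``chrN:start-end`` convention of array-CNV reports; conversion to
0-based half-open happens only at the BED boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "GenomicInterval",
    "normalize_chrom",
    "parse_region",
    "overlaps",
    "contains",
    "overlap_bp",
    "reciprocal_overlap",
    "size_mb",
    "write_bed",
]

#: Chromosome labels accepted after normalization.
ALLOWED_CHROMS = frozenset([str(i) for i in range(1, 23)] + ["X", "Y"])

_REGION_RE = re.compile(
    r"^(?P<chrom>[A-Za-z0-9]+):(?P<start>[\d,]+)-(?P<end>[\d,]+)$"
)


def normalize_chrom(label: str) -> str:
    """Normalize a chromosome label: strip any ``chr``/``Chr`` prefix,
    uppercase the sex chromosomes, and validate against 1-22/X/Y.
    """
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    s = s.upper() if s.upper() in ("X", "Y") else s.lstrip("0") or s
    if s not in ALLOWED_CHROMS:
        raise ValueError(f"unrecognized chromosome label: {label!r}")
    return s


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A closed genomic interval ``chrom:start-end`` (1-based, inclusive)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"end ({self.end}) must be >= start ({self.start})"
            )

    @property
    def length(self) -> int:
        """Number of bases covered (closed-interval arithmetic)."""
        return self.end - self.start + 1

    def __str__(self) -> str:
        return f"chr{self.chrom}:{self.start}-{self.end}"


def parse_region(text: str) -> GenomicInterval:
    """Parse a ``chrN:start-end`` string; thousands separators are allowed,
    e.g. ``"chr6:212,548-4,864,581"``.
    """
    m = _REGION_RE.match(text.strip())
    if m is None:
        raise ValueError(f"cannot parse region string: {text!r}")
    return GenomicInterval(
        chrom=m.group("chrom"),
        start=int(m.group("start").replace(",", "")),
        end=int(m.group("end").replace(",", "")),
    )


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two closed intervals share at least one base."""
    return a.chrom == b.chrom and a.start <= b.end and b.start <= a.end


def contains(outer: GenomicInterval, inner: GenomicInterval) -> bool:
    """True iff ``outer`` fully contains ``inner`` (same chromosome)."""
    return (
        outer.chrom == inner.chrom
        and outer.start <= inner.start
        and outer.end >= inner.end
    )


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by the two closed intervals (0 if disjoint)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start) + 1)


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    """min(shared/len(a), shared/len(b)); 1.0 for identical intervals."""
    shared = overlap_bp(a, b)
    if shared == 0:
        return 0.0
    return min(shared / a.length, shared / b.length)


def size_mb(iv: GenomicInterval) -> float:
    """CNV size in megabases, rounded to 2 decimals.

    Uses the ``end - start`` span (not the +1 base count): this is the
    convention under which the sizes printed in array-CNV reports are
    reproduced from their own coordinate strings.
    """
    return round((iv.end - iv.start) / 1e6, 2)


def write_bed(
    intervals: Iterable[GenomicInterval],
    path: str | Path,
    names: Sequence[str] | None = None,
) -> None:
    """Write intervals as BED (0-based half-open). With ``names``, BED4."""
    intervals = list(intervals)
    if names is not None and len(names) != len(intervals):
        raise ValueError("names must match intervals one-to-one")
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            row = [f"chr{iv.chrom}", str(iv.start - 1), str(iv.end)]
            if names is not None:
                row.append(str(names[i]))
            fh.write("\t".join(row) + "\n")
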
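"""Genomic interval containers and bp-level interval arithmetic.

All coordinates in the package are 0-based half-open (BED native). Any
1-based external dialect is converted at the I/O boundary, never here.
Chromosome names are matched by exact string equality: no "chr" aliasing,
because silent aliasing corrupts overlap counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
from intervaltree import IntervalTree

STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on a named chromosome.

    ``strand`` is one of ``+``, ``-`` or ``.`` (unstranded). ``name`` and
    ``score`` are optional BED-style annotations.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chromosome name must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True if the two intervals share at least one bp (strand-blind)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def sort_key(self) -> tuple:
        return (self.chrom, self.start, self.end)


@dataclass(frozen=True)
class Peak(GenomicInterval):
    """A called peak: a ``GenomicInterval`` plus narrowPeak-style statistics.

    ``summit_offset`` is the summit position relative to ``start``, or ``-1``
    when no summit is recorded (the narrowPeak convention).
    """

    signal_value: float = 0.0
    p_log10: float | None = None
    q_log10: float | None = None
    summit_offset: int = -1

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.summit_offset != -1 and not (
            0 <= self.summit_offset < self.end - self.start
        ):
            raise ValueError(
                f"summit offset {self.summit_offset} outside peak of length "
                f"{self.end - self.start}"
            )


@dataclass
class FragmentSet:
    """Deduplicated sequenced-fragment placements (the post-alignment unit).

    Fragments are unstranded intervals. ``labels`` optionally tags each
    placement as coming from the ``sample`` or the ``spike`` genome.
    """

    fragments: list[GenomicInterval]
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        if self.labels is not None:
            if len(self.labels) != len(self.fragments):
                raise ValueError("labels must match fragments one-to-one")
            bad = set(self.labels) - {"sample", "spike"}
            if bad:
                raise ValueError(f"invalid genome labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.fragments)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.fragments)

    def total_bp(self) -> int:
        return sum(len(f) for f in self.fragments)


# ---------------------------------------------------------------------------
# interval arithmetic on plain lists (bedtools-style merge/intersect)
# ---------------------------------------------------------------------------


def group_by_chrom(
    intervals: Iterable[GenomicInterval],
) -> dict[str, list[GenomicInterval]]:
    out: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        out.setdefault(iv.chrom, []).append(iv)
    return out


def merge_intervals(
    intervals: Iterable[GenomicInterval], merge_gap: int = 0
) -> list[GenomicInterval]:
    """Strand-blind bp union: overlapping (or gap <= merge_gap) intervals
    collapse into maximal runs. Output is sorted, unstranded and unnamed."""
    merged: list[GenomicInterval] = []
    by_chrom = group_by_chrom(intervals)
    for chrom in sorted(by_chrom):
        spans = sorted((iv.start, iv.end) for iv in by_chrom[chrom])
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s <= cur_e + merge_gap:
                cur_e = max(cur_e, e)
            else:
                merged.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append(GenomicInterval(chrom, cur_s, cur_e))
    return merged


def intersect_intervals(
    a: Iterable[GenomicInterval], b: Iterable[GenomicInterval]
) -> list[GenomicInterval]:
    """bp intersection of the merged unions of two interval sets."""
    am = group_by_chrom(merge_intervals(a))
    bm = group_by_chrom(merge_intervals(b))
    out: list[GenomicInterval] = []
    for chrom in sorted(set(am) & set(bm)):
        xs, ys = am[chrom], bm[chrom]
        i = j = 0
        while i < len(xs) and j < len(ys):
            s = max(xs[i].start, ys[j].start)
            e = min(xs[i].end, ys[j].end)
            if s < e:
                out.append(GenomicInterval(chrom, s, e))
            if xs[i].end <= ys[j].end:
                i += 1
            else:
                j += 1
    return out


def total_bp(intervals: Iterable[GenomicInterval]) -> int:
    """Total bp covered by the union of the intervals."""
    return sum(len(iv) for iv in merge_intervals(intervals))


def jaccard(a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]) -> float:
    """bp-level Jaccard index |A and B| / |A or B| of two interval sets."""
    if not a and not b:
        return 0.0
    inter = total_bp(intersect_intervals(a, b)) if (a and b) else 0
    union = total_bp(list(a) + list(b))
    return inter / union if union else 0.0


class GenomeIntervalIndex:
    """Per-chromosome interval tree for fast bp-overlap queries."""

    def __init__(self, intervals: Iterable[GenomicInterval]):
        self._trees: dict[str, IntervalTree] = {}
        for iv in intervals:
            self._trees.setdefault(iv.chrom, IntervalTree()).addi(
                iv.start, iv.end, iv
            )

    def overlaps(self, iv: GenomicInterval) -> bool:
        tree = self._trees.get(iv.chrom)
        return bool(tree is not None and tree.overlap(iv.start, iv.end))

    def overlapping(self, iv: GenomicInterval) -> list[GenomicInterval]:
        tree = self._trees.get(iv.chrom)
        if tree is None:
            return []
        hits = tree.overlap(iv.start, iv.end)
        return sorted((h.data for h in hits), key=GenomicInterval.sort_key)


def count_overlapping(
    query: Sequence[GenomicInterval], subject: Sequence[GenomicInterval]
) -> int:
    """Number of ``query`` intervals overlapping >=1 bp of any ``subject``.

    Vectorized against the merged subject union; suitable for the inner loop
    of randomization tests.
    """
    if not query or not subject:
        return 0
    merged = group_by_chrom(merge_intervals(subject))
    n = 0
    for chrom, qs in group_by_chrom(query).items():
        if chrom not in merged:
            continue
        s_starts = np.array([m.start for m in merged[chrom]])
        s_ends = np.array([m.end for m in merged[chrom]])
        q_starts = np.array([q.start for q in qs])
        q_ends = np.array([q.end for q in qs])
        # first merged subject whose end is past the query start
        j = np.searchsorted(s_ends, q_starts, side="right")
        ok = j < len(s_starts)
        hit = np.zeros(len(qs), dtype=bool)
        hit[ok] = s_starts[j[ok]] < q_ends[ok]
        n += int(hit.sum())
    return n
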
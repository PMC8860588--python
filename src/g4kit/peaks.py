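"""Peak-set operations: ranking, replicate consensus, overlap statistics,
randomization significance and functional annotation."""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from functools import reduce
from typing import Mapping, Sequence

import numpy as np

from .intervals import (
    GenomicInterval,
    GenomeIntervalIndex,
    Peak,
    count_overlapping,
    group_by_chrom,
    intersect_intervals,
    jaccard as _jaccard,
    merge_intervals,
)


@dataclass(frozen=True)
class OverlapSummary:
    """Peak-count partition of two sets plus their bp-level Jaccard index.

    A peak is counted in "both" if it overlaps >=1 bp of any peak in the
    other set; ``n_a_both`` counts from set A's side.
    """

    n_a_only: int
    n_a_both: int
    n_b_only: int
    jaccard: float


@dataclass
class RandomizationResult:
    """Outcome of a Monte-Carlo interval-overlap test.

    ``p_empirical = (1 + #{null >= observed}) / (n_iter + 1)`` — the add-one
    empirical p-value, never exactly zero.
    """

    observed: int
    null_values: np.ndarray
    p_empirical: float
    seed: int


@dataclass
class StateAnnotation:
    """Chromatin-state assignment of a peak set.

    ``fractions`` are over assigned peaks only and sum to 1 when any peak is
    assigned; peaks overlapping no state are counted in ``n_unannotated``.
    """

    counts: dict[str, int]
    fractions: dict[str, float]
    n_unannotated: int
    assignments: list[str] = field(default_factory=list)


def top_n_by_score(peaks: Sequence[Peak], n: int) -> list[Peak]:
    """The n highest-score peaks (BED column-5 score).

    Ties break by (chrom, start) ascending so the selection is stable across
    runs; if ``n`` exceeds the set size the whole set is returned (sorted).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ranked = sorted(
        peaks,
        key=lambda p: (-(p.score if p.score is not None else 0.0),
                       p.chrom, p.start, p.end),
    )
    return ranked[:n]


def consensus_peaks(
    replicates: Sequence[Sequence[GenomicInterval]],
    mode: str = "intersect",
) -> list[GenomicInterval]:
    """Concordant regions across >=2 replicate peak sets.

    ``mode="intersect"`` (default) returns the bp-intersection segments of
    all replicates' merged unions — every output base is covered by a peak
    in every replicate. ``mode="first-overlap-all"`` instead keeps the whole
    peaks of the first replicate that overlap every other replicate
    (the bedtools ``-u`` reading).
    """
    if len(replicates) < 2:
        raise ValueError("consensus requires at least 2 replicates")
    if mode == "intersect":
        merged = [merge_intervals(r) for r in replicates]
        return reduce(intersect_intervals, merged)
    if mode == "first-overlap-all":
        indexes = [GenomeIntervalIndex(r) for r in replicates[1:]]
        return [
            p
            for p in sorted(replicates[0], key=GenomicInterval.sort_key)
            if all(ix.overlaps(p) for ix in indexes)
        ]
    raise ValueError(f"unknown consensus mode {mode!r}")


def overlap_partition(
    set_a: Sequence[GenomicInterval], set_b: Sequence[GenomicInterval]
) -> OverlapSummary:
    """Partition peaks into A-only / both / B-only and compute bp Jaccard."""
    n_a_both = count_overlapping(set_a, set_b)
    n_b_both = count_overlapping(set_b, set_a)
    return OverlapSummary(
        n_a_only=len(set_a) - n_a_both,
        n_a_both=n_a_both,
        n_b_only=len(set_b) - n_b_both,
        jaccard=_jaccard(set_a, set_b),
    )


def _shuffle_chrom(
    lengths: Sequence[int],
    chrom_size: int,
    rng: np.random.Generator,
    max_tries: int = 10_000,
) -> list[tuple[int, int]]:
    """Place intervals of the given lengths uniformly without self-overlap
    (rejection sampling)."""
    starts: list[int] = []  # sorted placed starts
    ends: list[int] = []
    placed: list[tuple[int, int]] = []
    for length in lengths:
        if length > chrom_size:
            raise ValueError(
                f"interval of length {length} exceeds chromosome size "
                f"{chrom_size}"
            )
        for _ in range(max_tries):
            s = int(rng.integers(0, chrom_size - length + 1))
            e = s + length
            i = bisect.bisect_right(starts, s)
            clash = (i > 0 and ends[i - 1] > s) or (
                i < len(starts) and starts[i] < e
            )
            if not clash:
                starts.insert(i, s)
                ends.insert(i, e)
                placed.append((s, e))
                break
        else:
            raise RuntimeError(
                "could not place shuffled interval without overlap; "
                "chromosome too crowded"
            )
    return placed


def shuffle_intervals(
    intervals: Sequence[GenomicInterval],
    chrom_sizes: Mapping[str, int],
    rng: np.random.Generator,
) -> list[GenomicInterval]:
    """Length-preserving uniform relocation of each interval within its own
    chromosome, without self-overlap. Per-chromosome counts and lengths are
    preserved exactly."""
    out: list[GenomicInterval] = []
    for chrom in sorted(group_by_chrom(intervals)):
        ivs = group_by_chrom(intervals)[chrom]
        if chrom not in chrom_sizes:
            raise ValueError(f"no size known for chromosome {chrom!r}")
        spans = _shuffle_chrom(
            [len(iv) for iv in ivs], chrom_sizes[chrom], rng
        )
        out.extend(GenomicInterval(chrom, s, e) for s, e in spans)
    return out


def randomized_overlap_test(
    set_a: Sequence[GenomicInterval],
    set_b: Sequence[GenomicInterval],
    chrom_sizes: Mapping[str, int],
    n_iter: int = 999,
    seed: int = 0,
) -> RandomizationResult:
    """Monte-Carlo significance of the overlap between two peak sets.

    The statistic is the number of set-A peaks overlapping >=1 bp of set B.
    The null relocates each set-B interval uniformly within its chromosome
    (length-preserving, no self-overlap) ``n_iter`` times. Reproducible for
    a fixed seed.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    observed = count_overlapping(set_a, set_b)
    null = np.empty(n_iter, dtype=np.int64)
    for i in range(n_iter):
        shuffled = shuffle_intervals(set_b, chrom_sizes, rng)
        null[i] = count_overlapping(set_a, shuffled)
    p = (1 + int((null >= observed).sum())) / (n_iter + 1)
    return RandomizationResult(
        observed=observed, null_values=null, p_empirical=p, seed=seed
    )


def benjamini_hochberg(p_values: Sequence[float]) -> list[float]:
    """BH-adjusted q-values for a family of overlap tests."""
    from statsmodels.stats.multitest import multipletests

    if len(p_values) == 0:
        return []
    return list(multipletests(p_values, method="fdr_bh")[1])


def annotate_by_states(
    peaks: Sequence[GenomicInterval],
    states: Sequence[GenomicInterval],
) -> StateAnnotation:
    """Assign each peak to the chromatin state with maximal bp overlap.

    State labels come from the interval names of the segmentation. Ties
    break by first appearance in segmentation order; peaks with zero
    overlap are labelled ``unannotated`` and excluded from the fractions.
    """
    state_order: dict[str, int] = {}
    for st in states:
        label = st.name if st.name is not None else "."
        state_order.setdefault(label, len(state_order))
    index = GenomeIntervalIndex(states)
    counts: dict[str, int] = {}
    assignments: list[str] = []
    n_unannotated = 0
    for peak in peaks:
        bp: dict[str, int] = {}
        for st in index.overlapping(peak):
            label = st.name if st.name is not None else "."
            ov = min(peak.end, st.end) - max(peak.start, st.start)
            bp[label] = bp.get(label, 0) + ov
        if not bp:
            assignments.append("unannotated")
            n_unannotated += 1
            continue
        best = min(bp, key=lambda lab: (-bp[lab], state_order[lab]))
        assignments.append(best)
        counts[best] = counts.get(best, 0) + 1
    n_assigned = sum(counts.values())
    fractions = (
        {lab: c / n_assigned for lab, c in counts.items()} if n_assigned else {}
    )
    return StateAnnotation(
        counts=counts,
        fractions=fractions,
        n_unannotated=n_unannotated,
        assignments=assignments,
    )


def window_regions(
    points: Sequence[tuple[str, int, str]],
    flank: int,
    chrom_sizes: Mapping[str, int],
) -> list[GenomicInterval]:
    """Symmetric windows ``[pos - flank, pos + flank)`` around anchor points
    (TSS, enhancer centres), clipped to the chromosome and deduplicated.

    Duplicate anchor rows (e.g. one TSS shared by several transcripts)
    collapse to a single window.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    seen: set[tuple[str, int, int, str]] = set()
    out: list[GenomicInterval] = []
    for chrom, pos, strand in points:
        if chrom not in chrom_sizes:
            raise ValueError(f"no size known for chromosome {chrom!r}")
        size = chrom_sizes[chrom]
        if not (0 <= pos < size):
            raise ValueError(
                f"position {pos} outside chromosome {chrom} of size {size}"
            )
        start = max(0, pos - flank)
        end = min(size, pos + flank)
        if start == end:  # flank 0: keep a 1 bp anchor window
            end = min(size, start + 1)
        key = (chrom, start, end, strand)
        if key in seen:
            continue
        seen.add(key)
        out.append(GenomicInterval(chrom, start, end, strand))
    return sorted(out, key=GenomicInterval.sort_key)
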
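"""Coverage tracks, FriP, fingerprint curves, telomeric content, profile
matrices and a toy enrichment peak caller.

The coverage unit throughout is the sequenced fragment (tagmentation
products are paired-end by construction), never the single read. RPGC
("1x genome coverage") scales the raw per-bp depth so that the genome-wide
mean is 1: factor = effective_genome_size / total fragment bp.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .intervals import (
    FragmentSet,
    GenomicInterval,
    Peak,
    group_by_chrom,
    merge_intervals,
)
from .scan import reverse_complement
from .tracks import BinnedTrack


@dataclass
class FingerprintCurve:
    """Cumulative signal share over bins ranked by ascending coverage.

    ``xs`` is the cumulative fraction of ranked bins, ``ys`` the cumulative
    fraction of total signal; both run from 0 to 1 and the curve lies under
    the diagonal (more so the stronger the enrichment).
    """

    xs: np.ndarray
    ys: np.ndarray


def _depth_array(
    fragments: Sequence[GenomicInterval], chrom: str, size: int
) -> np.ndarray:
    """Per-bp fragment depth on one chromosome (fragments clipped to it)."""
    diff = np.zeros(size + 1)
    for f in fragments:
        s, e = max(0, f.start), min(size, f.end)
        if s < e:
            diff[s] += 1
            diff[e] -= 1
    return np.cumsum(diff)[:size]


def coverage_track(
    fragments: FragmentSet,
    chrom_sizes: Mapping[str, int],
    bin_size: int = 5,
    norm: str = "raw",
    effective_genome_size: int | None = None,
) -> BinnedTrack:
    """Binned fragment coverage, optionally RPGC-normalized.

    Raw values are the per-bin mean per-bp depth. ``norm="RPGC"`` multiplies
    by ``effective_genome_size / sum(fragment lengths)`` so the genome-wide
    mean becomes 1 (within 1/bin_size relative tolerance from the padded
    final bins). Fragments on chromosomes absent from ``chrom_sizes`` are
    ignored; the effective genome size has no hidden species table and must
    be supplied for RPGC.
    """
    if norm not in ("raw", "RPGC"):
        raise ValueError(f"norm must be 'raw' or 'RPGC', got {norm!r}")
    track = BinnedTrack(bin_size=bin_size, chrom_sizes=dict(chrom_sizes), norm=norm)
    by_chrom = group_by_chrom(fragments)
    factor = 1.0
    if norm == "RPGC":
        if effective_genome_size is None or effective_genome_size <= 0:
            raise ValueError("RPGC requires effective_genome_size > 0")
        total_bp = fragments.total_bp()
        if total_bp == 0:
            raise ValueError("RPGC factor undefined for zero fragments")
        factor = effective_genome_size / total_bp
    for chrom, size in chrom_sizes.items():
        depth = _depth_array(by_chrom.get(chrom, []), chrom, size)
        n_bins = len(track.data[chrom])
        padded = np.zeros(n_bins * bin_size)
        padded[:size] = depth
        track.data[chrom] = (
            padded.reshape(n_bins, bin_size).sum(axis=1) / bin_size * factor
        )
    return track


def _fragment_arrays(
    fragments: Sequence[GenomicInterval],
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    out = {}
    for chrom, frs in group_by_chrom(fragments).items():
        out[chrom] = (
            np.array([f.start for f in frs]),
            np.array([f.end for f in frs]),
        )
    return out


def frip(fragments: FragmentSet, peaks: Sequence[GenomicInterval]) -> float:
    """Fraction of fragments overlapping >=1 bp of any peak.

    This is an overlap test, not a bp test, so it is invariant under merging
    of the peak set.
    """
    if len(fragments) == 0:
        raise ValueError("FriP undefined for an empty fragment set")
    if not peaks:
        return 0.0
    merged = group_by_chrom(merge_intervals(peaks))
    n_in = 0
    for chrom, (starts, ends) in _fragment_arrays(list(fragments)).items():
        if chrom not in merged:
            continue
        p_starts = np.array([p.start for p in merged[chrom]])
        p_ends = np.array([p.end for p in merged[chrom]])
        j = np.searchsorted(p_ends, starts, side="right")
        ok = j < len(p_starts)
        hit = np.zeros(len(starts), dtype=bool)
        hit[ok] = p_starts[j[ok]] < ends[ok]
        n_in += int(hit.sum())
    return n_in / len(fragments)


def fragment_bin_counts(
    fragments: FragmentSet,
    chrom_sizes: Mapping[str, int],
    bin_size: int,
) -> BinnedTrack:
    """Fragment counts per bin (each fragment assigned by its midpoint)."""
    track = BinnedTrack(bin_size=bin_size, chrom_sizes=dict(chrom_sizes))
    for chrom, (starts, ends) in _fragment_arrays(list(fragments)).items():
        if chrom not in track.data:
            continue
        mids = np.clip((starts + ends) // 2, 0, chrom_sizes[chrom] - 1)
        track.data[chrom] = np.bincount(
            mids // bin_size, minlength=len(track.data[chrom])
        ).astype(float)
    return track


def fingerprint(
    fragments: FragmentSet,
    chrom_sizes: Mapping[str, int],
    bin_size: int = 500,
) -> FingerprintCurve:
    """Fingerprint curve: cumulative fragment-count share by ranked bins.

    Bins are sorted by ascending count; a uniform library tracks the
    diagonal while a focal one hugs the x axis until the final bins. The
    curve is invariant to chromosome ordering and to permutations of
    equal-count bins. Raises when no fragment falls on the given genome.
    """
    counts = fragment_bin_counts(fragments, chrom_sizes, bin_size).concatenated()
    total = counts.sum()
    if total == 0:
        raise ValueError("fingerprint undefined: zero total bin count")
    ranked = np.sort(counts)
    xs = np.concatenate([[0.0], np.arange(1, len(ranked) + 1) / len(ranked)])
    ys = np.concatenate([[0.0], np.cumsum(ranked) / total])
    return FingerprintCurve(xs=xs, ys=ys)


def telomeric_fraction(
    reads: Sequence[str],
    unit: str = "TTAGGG",
    min_tandem: int = 3,
) -> float:
    """Fraction of reads containing >= min_tandem consecutive copies of the
    telomeric repeat unit or of its reverse complement.

    Tandem string matching stands in for alignment against a telomeric
    pseudogenome; requiring a few consecutive units (default 3) mimics an
    aligner's seed requirement while tolerating reads that enter or leave
    the repeat array. Invariant to read orientation.
    """
    if min_tandem < 1:
        raise ValueError("min_tandem must be >= 1")
    if not reads:
        raise ValueError("telomeric fraction undefined for an empty read list")
    fwd = unit.upper() * min_tandem
    rev = reverse_complement(unit.upper()) * min_tandem
    n_hit = sum(1 for r in reads if fwd in r.upper() or rev in r.upper())
    return n_hit / len(reads)


def profile_matrix(
    track: BinnedTrack,
    windows: Sequence[GenomicInterval],
    n_bins: int,
) -> np.ndarray:
    """Mean track value per window-bin; rows are windows, columns run 5'->3'.

    All windows must share one width divisible by ``n_bins``. Minus-strand
    windows are column-reversed. Parts of a window that fall off the
    chromosome are NaN-padded.
    """
    if not windows:
        return np.zeros((0, n_bins))
    width = len(windows[0])
    if any(len(w) != width for w in windows):
        raise ValueError("all profile windows must have the same width")
    if width % n_bins != 0:
        raise ValueError(f"window width {width} not divisible by {n_bins} bins")
    col_bp = width // n_bins
    matrix = np.full((len(windows), n_bins), np.nan)
    for row, win in enumerate(windows):
        if win.chrom not in track.data:
            continue
        values = track.data[win.chrom]
        size = track.chrom_sizes[win.chrom]
        # per-bp values for the window, NaN outside the chromosome
        bp = np.full(width, np.nan)
        lo, hi = max(0, win.start), min(size, win.end)
        if lo < hi:
            pos = np.arange(lo, hi)
            bp[pos - win.start] = values[pos // track.bin_size]
        cols = bp.reshape(n_bins, col_bp)
        counts = (~np.isnan(cols)).sum(axis=1)
        sums = np.nansum(cols, axis=1)
        # all-NaN columns (fully off-chromosome) stay NaN without warning
        row_vals = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        matrix[row] = row_vals[::-1] if win.strand == "-" else row_vals
    return matrix


def call_enriched_bins(
    track: BinnedTrack,
    z_threshold: float = 3.0,
    min_run: int = 2,
    merge_gap: int = 1,
    max_score: int = 1000,
) -> list[Peak]:
    """Toy enrichment caller: contiguous runs of unusually covered bins.

    A bin is enriched when its value exceeds mean + z_threshold * sd of the
    NONZERO bins (sparse tagmentation leaves most bins empty; a global sd
    would be deflated). Enriched runs separated by <= merge_gap bins merge,
    and merged runs shorter than min_run bins are dropped. The BED score is
    the peak's mean fold over the genome-wide mean, scaled by 100 and capped
    at 1000; ``signal_value`` carries the unscaled fold and the summit is
    the maximal bin. A constant track yields no peaks.

    This is pipeline plumbing — a stand-in for a real peak caller so the
    synthetic workflow is closed — not a statistical model of tagmentation.
    """
    if track.n_bins() == 0:
        raise ValueError("cannot call peaks on an empty track")
    pooled = track.concatenated()
    nonzero = pooled[pooled > 0]
    if len(nonzero) == 0:
        return []
    threshold = nonzero.mean() + z_threshold * nonzero.std()
    genome_mean = pooled.mean()
    peaks: list[Peak] = []
    for chrom in sorted(track.data):
        values = track.data[chrom]
        above = np.flatnonzero(values > threshold)
        if len(above) == 0:
            continue
        # merge consecutive enriched bins across small gaps
        breaks = np.flatnonzero(np.diff(above) > merge_gap + 1)
        groups = np.split(above, breaks + 1)
        for grp in groups:
            first, last = int(grp[0]), int(grp[-1])
            if last - first + 1 < min_run:
                continue
            start = first * track.bin_size
            end = min((last + 1) * track.bin_size, track.chrom_sizes[chrom])
            fold = float(values[first : last + 1].mean() / genome_mean) \
                if genome_mean > 0 else 0.0
            summit_bin = first + int(np.argmax(values[first : last + 1]))
            peaks.append(
                Peak(
                    chrom,
                    start,
                    end,
                    ".",
                    name=f"peak_{chrom}_{start}",
                    score=float(min(max_score, round(100 * fold))),
                    signal_value=fold,
                    summit_offset=min(
                        summit_bin * track.bin_size - start, end - start - 1
                    ),
                )
            )
    return peaks
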
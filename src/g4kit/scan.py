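"""Putative G-quadruplex sequence (PQS) scanning.

Four motif classes are recognised:

* ``canonical`` — four runs of >=3 G separated by loops of 1-7 nt
  (G3+ L1-7 x3 G3+), the classic intramolecular quadruplex motif.
* ``extended`` — the same runs with relaxed loops of 1-12 nt.
* ``two_tetrad`` — runs of exactly two G with loops of 1-12 nt and at least
  four runs, permitting quadruplexes of only two stacked tetrads. The motif
  is read as a repeated (run + loop) group, ``(G{2} L{1,12}){3,} G{2}``:
  a literal nesting of the two quantifiers is not a valid pattern, so the
  repeated-group reading is the only consistent one and is used throughout.
* ``interstrand`` — four runs contributed by both duplex strands. A
  composition string over {A, B} assigns each of the four blocks to a G-run
  on the reference strand (A = G3+) or a C-run (B = C3+, i.e. a G-run on the
  opposite strand), with loops of 1-7 nt in reference coordinates. Only the
  eight A-leading compositions are scanned; B-leading compositions are their
  reverse-complement mirrors and would double-count.

Matching follows regex-engine semantics: leftmost, greedy, non-overlapping
per strand. Loops draw from {A, C, G, T} only — N never counts as a loop or
run base, so gapped assemblies do not inflate calls. An ``overlapping`` mode
enumerates every distinct (start, end) placement instead; it backs the
containment property (every canonical placement is an extended placement).

Strand conventions
------------------
Minus-strand matches of the intra-strand classes are defined as the
G-pattern scan of the reverse complement, mirrored back into reference
coordinates. Inter-strand compositions are scanned in a canonical
orientation per dual pair (the lexicographically smaller of a composition
and its reverse-complement dual scans forward; the other is obtained by
mirroring). Both conventions make the strand/composition mirror symmetry of
the scanner exact by construction rather than only approximately true.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .intervals import GenomicInterval, GenomeIntervalIndex, merge_intervals
from .io import SequenceRecord
from .tracks import BinnedTrack

INTRASTRAND_CLASSES = ("canonical", "extended", "two_tetrad")
INTERSTRAND_COMPOSITIONS = (
    "AAAA",
    "AAAB",
    "AABA",
    "AABB",
    "ABAA",
    "ABAB",
    "ABBA",
    "ABBB",
)
#: the seven trans-strand compositions (AAAA is the canonical motif itself)
NONCANONICAL_COMPOSITIONS = tuple(
    c for c in INTERSTRAND_COMPOSITIONS if c != "AAAA"
)

_LOOP_CLASS = "[ACGT]"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement over the {A, C, G, T, N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PQSPatternSpec:
    """One motif class: run length, loop range and block layout.

    ``blocks`` is the number of runs for the fixed classes and the minimum
    number for ``two_tetrad`` (``variable_blocks=True``). ``run_exact`` marks
    the two-tetrad convention that a block consumes exactly ``min_run``
    bases, with greedy loops absorbing any surplus G.
    """

    class_id: str
    min_run: int
    loop_min: int
    loop_max: int
    blocks: int
    composition: str = "AAAA"
    variable_blocks: bool = False
    run_exact: bool = False

    def __post_init__(self) -> None:
        if self.loop_min > self.loop_max:
            raise ValueError("loop_min must be <= loop_max")
        if self.min_run not in (2, 3):
            raise ValueError("min_run must be 2 or 3")
        if set(self.composition) - {"A", "B"}:
            raise ValueError("composition must be over {A, B}")

    @classmethod
    def for_class(
        cls, class_id: str, composition: str | None = None
    ) -> "PQSPatternSpec":
        if class_id == "canonical":
            return cls("canonical", 3, 1, 7, 4)
        if class_id == "extended":
            return cls("extended", 3, 1, 12, 4)
        if class_id == "two_tetrad":
            return cls(
                "two_tetrad", 2, 1, 12, 4, variable_blocks=True, run_exact=True
            )
        if class_id == "interstrand":
            if composition not in INTERSTRAND_COMPOSITIONS:
                raise ValueError(
                    f"inter-strand composition must be one of "
                    f"{INTERSTRAND_COMPOSITIONS}, got {composition!r}"
                )
            return cls("interstrand", 3, 1, 7, 4, composition=composition)
        raise ValueError(f"unknown PQS class {class_id!r}")


@dataclass(frozen=True)
class PQSMatch(GenomicInterval):
    """A scanner hit: interval plus class, composition and matched sequence.

    ``matched_seq`` is always the reference-strand slice ``[start, end)``.
    ``composition`` is set for classes with a fixed A/B block layout
    (canonical/extended report ``AAAA``); two-tetrad matches have a variable
    block count and leave it ``None``.
    """

    class_id: str = "canonical"
    composition: str | None = None
    matched_seq: str = ""


# ---------------------------------------------------------------------------
# pattern construction
# ---------------------------------------------------------------------------


def _run_regex(base: str, spec: PQSPatternSpec) -> str:
    if spec.run_exact:
        return f"{base}{{{spec.min_run}}}"
    return f"{base}{{{spec.min_run},}}"


def _loop_regex(spec: PQSPatternSpec) -> str:
    return f"{_LOOP_CLASS}{{{spec.loop_min},{spec.loop_max}}}"


def compiled_pattern(spec: PQSPatternSpec, g_base: str = "G") -> re.Pattern:
    """The class's regex on the given run base ('G' normally)."""
    c_base = "C" if g_base == "G" else "G"
    loop = _loop_regex(spec)
    if spec.variable_blocks:
        run = _run_regex(g_base, spec)
        return re.compile(f"(?:{run}{loop}){{{spec.blocks - 1},}}{run}")
    runs = [
        _run_regex(g_base if letter == "A" else c_base, spec)
        for letter in spec.composition
    ]
    return re.compile(loop.join(runs))


def _dual_composition(composition: str) -> str:
    """Reverse-complement dual: reverse the block order and swap A <-> B."""
    swap = {"A": "B", "B": "A"}
    return "".join(swap[c] for c in reversed(composition))


# ---------------------------------------------------------------------------
# enumeration of all placements (overlapping mode)
# ---------------------------------------------------------------------------


def _max_run_lengths(seq: str, base: str) -> np.ndarray:
    """lengths[i] = length of the maximal run of ``base`` starting at i."""
    n = len(seq)
    out = np.zeros(n + 1, dtype=np.int64)
    for i in range(n - 1, -1, -1):
        if seq[i] == base:
            out[i] = out[i + 1] + 1
    return out


def _max_loop_lengths(seq: str) -> np.ndarray:
    """lengths[i] = maximal stretch of loop-alphabet (non-N) bases from i."""
    n = len(seq)
    out = np.zeros(n + 1, dtype=np.int64)
    for i in range(n - 1, -1, -1):
        if seq[i] != "N":
            out[i] = out[i + 1] + 1
    return out


def _enumerate_fixed(
    seq: str, spec: PQSPatternSpec, g_base: str = "G"
) -> set[tuple[int, int]]:
    """All distinct (start, end) placements of a fixed-block pattern."""
    c_base = "C" if g_base == "G" else "G"
    bases = [g_base if letter == "A" else c_base for letter in spec.composition]
    run_len = {b: _max_run_lengths(seq, b) for b in set(bases)}
    loop_len = _max_loop_lengths(seq)
    memo: dict[tuple[int, int], frozenset[int]] = {}

    def ends(block: int, pos: int) -> frozenset[int]:
        key = (block, pos)
        if key in memo:
            return memo[key]
        result: set[int] = set()
        max_run = int(run_len[bases[block]][pos])
        run_lengths = (
            [spec.min_run]
            if spec.run_exact
            else range(spec.min_run, max_run + 1)
        )
        if max_run >= spec.min_run:
            for rl in run_lengths:
                after_run = pos + rl
                if block == len(bases) - 1:
                    result.add(after_run)
                    continue
                max_loop = min(spec.loop_max, int(loop_len[after_run]))
                for ll in range(spec.loop_min, max_loop + 1):
                    result.update(ends(block + 1, after_run + ll))
        memo[key] = frozenset(result)
        return memo[key]

    first = bases[0]
    placements: set[tuple[int, int]] = set()
    for start in range(len(seq)):
        if run_len[first][start] >= spec.min_run:
            for end in ends(0, start):
                placements.add((start, end))
    return placements


def _enumerate_variable(
    seq: str, spec: PQSPatternSpec, g_base: str = "G"
) -> set[tuple[int, int]]:
    """All distinct (start, end) placements of the repeated-group pattern."""
    run_len = _max_run_lengths(seq, g_base)
    loop_len = _max_loop_lengths(seq)
    unit_memo: dict[int, frozenset[int]] = {}

    def unit_ends(pos: int) -> frozenset[int]:
        """Positions after one (run + loop) group starting at pos."""
        if pos in unit_memo:
            return unit_memo[pos]
        result: set[int] = set()
        if run_len[pos] >= spec.min_run:
            after_run = pos + spec.min_run
            max_loop = min(spec.loop_max, int(loop_len[after_run]))
            for ll in range(spec.loop_min, max_loop + 1):
                result.add(after_run + ll)
        unit_memo[pos] = frozenset(result)
        return unit_memo[pos]

    min_units = spec.blocks - 1
    placements: set[tuple[int, int]] = set()
    for start in range(len(seq)):
        if run_len[start] < spec.min_run:
            continue
        frontier = {start}
        for _ in range(min_units):
            frontier = set().union(*(unit_ends(p) for p in frontier)) \
                if frontier else set()
        seen: set[int] = set()
        while frontier:
            for pos in frontier:
                if run_len[pos] >= spec.min_run:
                    placements.add((start, pos + spec.min_run))
            seen |= frontier
            frontier = (
                set().union(*(unit_ends(p) for p in frontier)) - seen
                if frontier
                else set()
            )
    return placements


def _enumerate_all(
    seq: str, spec: PQSPatternSpec, g_base: str = "G"
) -> set[tuple[int, int]]:
    if spec.variable_blocks:
        return _enumerate_variable(seq, spec, g_base)
    return _enumerate_fixed(seq, spec, g_base)


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------


def _forward_spans(
    seq: str, spec: PQSPatternSpec, overlapping: bool
) -> list[tuple[int, int]]:
    if overlapping:
        return sorted(_enumerate_all(seq, spec))
    pattern = compiled_pattern(spec)
    return [(m.start(), m.end()) for m in pattern.finditer(seq)]


def _mirror(spans: Iterable[tuple[int, int]], length: int) -> list[tuple[int, int]]:
    return sorted((length - e, length - s) for s, e in spans)


def scan_intrastrand(
    record: SequenceRecord,
    class_id: str,
    overlapping: bool = False,
    strands: Sequence[str] = ("+", "-"),
) -> list[PQSMatch]:
    """Scan one chromosome for an intra-strand PQS class on one or both strands.

    Default matching is leftmost, greedy and non-overlapping per strand;
    ``overlapping=True`` reports every distinct placement instead. Matches
    are returned in (start, end, strand) order with reference-strand
    ``matched_seq``.
    """
    if class_id not in INTRASTRAND_CLASSES:
        raise ValueError(
            f"intra-strand class must be one of {INTRASTRAND_CLASSES}, "
            f"got {class_id!r}"
        )
    spec = PQSPatternSpec.for_class(class_id)
    composition = "AAAA" if not spec.variable_blocks else None
    seq = record.sequence
    matches: list[PQSMatch] = []
    if "+" in strands:
        for s, e in _forward_spans(seq, spec, overlapping):
            matches.append(
                PQSMatch(
                    record.name,
                    s,
                    e,
                    "+",
                    class_id=class_id,
                    composition=composition,
                    matched_seq=seq[s:e],
                )
            )
    if "-" in strands:
        rc = reverse_complement(seq)
        for s, e in _mirror(_forward_spans(rc, spec, overlapping), len(seq)):
            matches.append(
                PQSMatch(
                    record.name,
                    s,
                    e,
                    "-",
                    class_id=class_id,
                    composition=composition,
                    matched_seq=seq[s:e],
                )
            )
    return sorted(matches, key=lambda m: (m.start, m.end, m.strand))


def _scan_interstrand_any(
    record: SequenceRecord, composition: str, overlapping: bool = False
) -> list[tuple[int, int]]:
    """Inter-strand spans for any {A,B} composition (internal; no validation
    against the public eight). Scans in the canonical orientation of the
    composition's dual pair."""
    dual = _dual_composition(composition)
    seq = record.sequence
    if composition <= dual:
        spec = PQSPatternSpec("interstrand", 3, 1, 7, 4, composition=composition)
        return sorted(_forward_spans(seq, spec, overlapping))
    spec = PQSPatternSpec("interstrand", 3, 1, 7, 4, composition=dual)
    rc = reverse_complement(seq)
    return _mirror(_forward_spans(rc, spec, overlapping), len(seq))


def scan_interstrand(
    record: SequenceRecord, composition: str, overlapping: bool = False
) -> list[PQSMatch]:
    """Scan for one of the eight inter-strand compositions.

    Block A is a G-run, block B a C-run, all in reference-strand
    coordinates. Strand is "." except for AAAA, which is the canonical
    intra-strand motif on the plus strand and reports identical intervals to
    ``scan_intrastrand(..., "canonical", strands=("+",))``.
    """
    if composition not in INTERSTRAND_COMPOSITIONS:
        raise ValueError(
            f"composition must be one of {INTERSTRAND_COMPOSITIONS}, "
            f"got {composition!r}"
        )
    strand = "+" if composition == "AAAA" else "."
    seq = record.sequence
    return [
        PQSMatch(
            record.name,
            s,
            e,
            strand,
            class_id="interstrand",
            composition=composition,
            matched_seq=seq[s:e],
        )
        for s, e in _scan_interstrand_any(record, composition, overlapping)
    ]


def scan_genome(
    records: Sequence[SequenceRecord],
    class_id: str,
    composition: str | None = None,
    overlapping: bool = False,
    strands: Sequence[str] = ("+", "-"),
) -> list[PQSMatch]:
    """Scan every chromosome for one class (all 8 compositions if
    ``class_id='interstrand'`` and no composition is given)."""
    matches: list[PQSMatch] = []
    for record in records:
        if class_id == "interstrand":
            comps = (
                [composition] if composition else list(INTERSTRAND_COMPOSITIONS)
            )
            for comp in comps:
                matches.extend(scan_interstrand(record, comp, overlapping))
        else:
            matches.extend(
                scan_intrastrand(record, class_id, overlapping, strands)
            )
    return matches


# ---------------------------------------------------------------------------
# derived tracks and statistics
# ---------------------------------------------------------------------------


def pqs_union(
    matches_by_class: Mapping[str, Sequence[GenomicInterval]],
    classes: Iterable[str] | None = None,
) -> list[GenomicInterval]:
    """bp-merged union of the selected match classes (all by default)."""
    selected = list(matches_by_class) if classes is None else list(classes)
    pooled: list[GenomicInterval] = []
    for key in selected:
        pooled.extend(matches_by_class[key])
    if not pooled:
        return []
    return merge_intervals(pooled)


def pqs_coverage(
    matches: Sequence[GenomicInterval],
    chrom_sizes: Mapping[str, int],
    bin_size: int,
) -> BinnedTrack:
    """Per-bin motif occupancy: bp covered by >=1 match over bin size, in [0, 1].

    Overlapping matches count each base once (the union is taken first).
    """
    track = BinnedTrack(
        bin_size=bin_size, chrom_sizes=dict(chrom_sizes), norm="occupancy"
    )
    for iv in merge_intervals(matches):
        if iv.chrom not in track.data:
            continue
        size = chrom_sizes[iv.chrom]
        start, end = max(0, iv.start), min(size, iv.end)
        first, last = start // bin_size, (end - 1) // bin_size
        for b in range(first, last + 1):
            lo = max(start, b * bin_size)
            hi = min(end, (b + 1) * bin_size)
            track.data[iv.chrom][b] += (hi - lo) / bin_size
    return track


def cpg_track(record: SequenceRecord) -> list[GenomicInterval]:
    """One 2-bp interval per CG dinucleotide (plus strand); overlap-free by
    construction since CG cannot overlap itself."""
    seq = record.sequence
    out = []
    pos = seq.find("CG")
    while pos != -1:
        out.append(GenomicInterval(record.name, pos, pos + 2, "+"))
        pos = seq.find("CG", pos + 1)
    return out


def fraction_peaks_with_pqs(
    peaks: Sequence[GenomicInterval],
    pqs_intervals: Sequence[GenomicInterval],
) -> float:
    """Fraction of peaks overlapping >=1 bp of any PQS interval."""
    if not peaks:
        raise ValueError("fraction undefined for an empty peak list")
    if not pqs_intervals:
        return 0.0
    index = GenomeIntervalIndex(merge_intervals(pqs_intervals))
    return sum(index.overlaps(p) for p in peaks) / len(peaks)
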
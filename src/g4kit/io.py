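"""Readers and writers for the plain-text genomics formats the toolkit uses.

FASTA, BED6, ENCODE narrowPeak (10 columns), bedGraph, fragment BED
(chrom/start/end) and FASTQ are supported; an optional SAM adapter converts
properly paired alignments into fragment intervals. Everything is 0-based
half-open internally. Output files are written atomically
(temp-then-rename) so a crashed run never leaves a truncated file behind.
"""

from __future__ import annotations

import os
import tempfile
from contextlib import contextmanager
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .intervals import (
    FragmentSet,
    GenomicInterval,
    GenomeIntervalIndex,
    Peak,
)
from .tracks import BinnedTrack

_VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence over {A, C, G, T, N}, stored uppercase."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("sequence name must be non-empty")
        seq = self.sequence.upper()
        if not seq:
            raise ValueError(f"{self.name}: empty sequence")
        bad = set(seq) - _VALID_BASES
        if bad:
            raise ValueError(f"{self.name}: invalid characters {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@contextmanager
def atomic_open(path: str | Path) -> Iterator:
    """Write to a temp file in the target directory, rename on success."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(
        dir=str(path.parent) or ".", prefix=path.name + ".", suffix=".tmp"
    )
    try:
        with os.fdopen(fd, "w") as handle:
            yield handle
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into uppercase :class:`SequenceRecord` objects.

    Raises on an empty file and on duplicate headers (naming the header),
    since a genome with two chromosomes of the same name is unusable for
    interval arithmetic.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA header: {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, str(rec.seq)))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with atomic_open(path) as handle:
        SeqIO.write(
            (
                _BioSeqRecord(Seq(r.sequence), id=r.name, description="")
                for r in records
            ),
            handle,
            "fasta",
        )


def read_fastq(path: str | Path) -> list[str]:
    """Read sequences (only) from a FASTQ file."""
    return [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fastq")]


def write_fastq(
    reads: Sequence[str], path: str | Path, name_prefix: str = "read"
) -> None:
    with atomic_open(path) as handle:
        for i, seq in enumerate(reads):
            handle.write(f"@{name_prefix}{i}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# BED dialects
# ---------------------------------------------------------------------------


def _parse_int(text: str, what: str, line_no: int) -> int:
    try:
        return int(text)
    except ValueError:
        raise ValueError(
            f"line {line_no}: non-integer {what}: {text!r}"
        ) from None


def _parse_score(text: str) -> float | None:
    return None if text in (".", "") else float(text)


def read_bed(path: str | Path, kind: str = "bed6") -> list[Peak]:
    """Read a BED6 or 10-column ENCODE narrowPeak file as :class:`Peak` rows.

    BED6 accepts 3-6 columns (missing strand becomes "."); narrowPeak
    requires exactly 10. Column 5 maps to ``score``, narrowPeak column 7 to
    ``signal_value`` and column 10 to ``summit_offset``. Malformed
    coordinates raise with the offending line number.
    """
    if kind not in ("bed6", "narrowPeak"):
        raise ValueError(f"unknown BED dialect {kind!r}")
    peaks: list[Peak] = []
    with open(path) as handle:
        for line_no, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if kind == "bed6" and len(cols) < 3:
                raise ValueError(f"line {line_no}: fewer than 3 BED columns")
            if kind == "narrowPeak" and len(cols) != 10:
                raise ValueError(
                    f"line {line_no}: narrowPeak needs exactly 10 columns, "
                    f"got {len(cols)}"
                )
            chrom = cols[0]
            start = _parse_int(cols[1], "start", line_no)
            end = _parse_int(cols[2], "end", line_no)
            if start >= end:
                raise ValueError(
                    f"line {line_no}: start {start} >= end {end}"
                )
            name = cols[3] if len(cols) > 3 and cols[3] != "." else None
            score = _parse_score(cols[4]) if len(cols) > 4 else None
            strand = cols[5] if len(cols) > 5 and cols[5] in ("+", "-") else "."
            if kind == "bed6":
                peaks.append(
                    Peak(chrom, start, end, strand, name, score)
                )
            else:
                summit = _parse_int(cols[9], "summit offset", line_no)
                peaks.append(
                    Peak(
                        chrom,
                        start,
                        end,
                        strand,
                        name,
                        score,
                        signal_value=float(cols[6]),
                        p_log10=_parse_score(cols[7]),
                        q_log10=_parse_score(cols[8]),
                        summit_offset=summit,
                    )
                )
    return peaks


def _fmt_score(score: float | None) -> str:
    if score is None:
        return "."
    if float(score).is_integer():
        return str(int(score))
    return repr(float(score))


def write_bed(
    intervals: Sequence[GenomicInterval],
    path: str | Path,
    kind: str = "bed6",
) -> None:
    """Write intervals as BED6 or narrowPeak. Empty input gives an empty file."""
    if kind not in ("bed6", "narrowPeak"):
        raise ValueError(f"unknown BED dialect {kind!r}")
    with atomic_open(path) as handle:
        for iv in intervals:
            name = iv.name if iv.name is not None else "."
            base = (
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t"
                f"{_fmt_score(iv.score)}\t{iv.strand}"
            )
            if kind == "bed6":
                handle.write(base + "\n")
            else:
                if not isinstance(iv, Peak):
                    raise ValueError("narrowPeak output requires Peak records")
                handle.write(
                    base
                    + f"\t{repr(float(iv.signal_value))}"
                    + f"\t{_fmt_score(iv.p_log10)}"
                    + f"\t{_fmt_score(iv.q_log10)}"
                    + f"\t{iv.summit_offset}\n"
                )


def read_fragment_bed(path: str | Path) -> FragmentSet:
    """Read a minimal fragment BED (chrom, start, end) into a FragmentSet."""
    ivs = [
        GenomicInterval(p.chrom, p.start, p.end) for p in read_bed(path, "bed6")
    ]
    return FragmentSet(ivs)


def write_fragment_bed(fragments: FragmentSet, path: str | Path) -> None:
    with atomic_open(path) as handle:
        for frag in fragments:
            handle.write(f"{frag.chrom}\t{frag.start}\t{frag.end}\n")


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------


def write_bedgraph(
    track: BinnedTrack, path: str | Path, collapse: bool = True
) -> None:
    """Write a binned track as bedGraph.

    With ``collapse=True`` runs of equal-valued adjacent bins (zero runs in
    particular) are emitted as one line. Intervals are clipped to the
    chromosome end.
    """
    with atomic_open(path) as handle:
        for chrom in sorted(track.data):
            values = track.data[chrom]
            size = track.chrom_sizes[chrom]
            run_start = 0
            for i in range(1, len(values) + 1):
                boundary = (
                    i == len(values)
                    or not collapse
                    or values[i] != values[run_start]
                )
                if boundary:
                    s = run_start * track.bin_size
                    e = min(i * track.bin_size, size)
                    handle.write(f"{chrom}\t{s}\t{e}\t{values[run_start]:g}\n")
                    run_start = i


def read_bedgraph(path: str | Path) -> list[tuple[str, int, int, float]]:
    out = []
    with open(path) as handle:
        for line_no, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            cols = line.split("\t")
            if len(cols) != 4:
                raise ValueError(f"line {line_no}: bedGraph needs 4 columns")
            out.append(
                (
                    cols[0],
                    _parse_int(cols[1], "start", line_no),
                    _parse_int(cols[2], "end", line_no),
                    float(cols[3]),
                )
            )
    return out


def track_from_bedgraph(
    entries: Sequence[tuple[str, int, int, float]],
    chrom_sizes: dict[str, int],
    bin_size: int,
    norm: str = "raw",
) -> BinnedTrack:
    """Rebuild a :class:`BinnedTrack` from bedGraph rows aligned to bins."""
    track = BinnedTrack(bin_size=bin_size, chrom_sizes=dict(chrom_sizes), norm=norm)
    for chrom, start, end, value in entries:
        if chrom not in track.data:
            raise ValueError(f"bedGraph chromosome {chrom!r} not in chrom sizes")
        first = start // bin_size
        last = -(-end // bin_size)
        track.data[chrom][first:last] = value
    return track


# ---------------------------------------------------------------------------
# chrom sizes, blacklist filtering, SAM adapter
# ---------------------------------------------------------------------------


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column (chrom, size) TSV, as produced by samtools faidx."""
    sizes: dict[str, int] = {}
    with open(path) as handle:
        for line_no, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise ValueError(f"line {line_no}: need chrom<TAB>size")
            if cols[0] in sizes:
                raise ValueError(f"line {line_no}: duplicate chromosome {cols[0]!r}")
            sizes[cols[0]] = _parse_int(cols[1], "size", line_no)
    return sizes


def filter_blacklist(
    intervals: Sequence[GenomicInterval],
    blacklist: Sequence[GenomicInterval],
) -> list[GenomicInterval]:
    """Drop every interval overlapping >=1 bp of the blacklist, keep order.

    Half-open abutment (interval ending where a blacklist region starts) is
    not an overlap.
    """
    index = GenomeIntervalIndex(blacklist)
    return [iv for iv in intervals if not index.overlaps(iv)]


def read_sam_fragments(path: str | Path) -> FragmentSet:
    """Convert properly paired SAM alignments into fragment intervals.

    Each proper pair contributes one interval spanning the outer template
    coordinates (taken from the leftmost mate's positive TLEN). This adapter
    exists so aligned data can enter the pipeline without a BAM toolchain;
    the core pipeline consumes fragment BED.
    """
    import pysam

    fragments: list[GenomicInterval] = []
    with pysam.AlignmentFile(str(path), "r") as sam:
        for read in sam:
            if (
                read.is_unmapped
                or not read.is_proper_pair
                or read.template_length <= 0
            ):
                continue
            start = read.reference_start
            fragments.append(
                GenomicInterval(
                    read.reference_name, start, start + read.template_length
                )
            )
    return FragmentSet(fragments)
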
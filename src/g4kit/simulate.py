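"""Synthetic genomes, truth PQS annotations and enrichment-structured
fragment libraries.

The generator makes the whole pipeline testable without downloads. Its
central trick is G-run suppression: background sequence never contains a
run of three or more G (or C), so every canonical-motif hit on a synthetic
genome is an implanted site and truth equals scanner output by
construction. Implants sit in short A/T guard bands so greedy loops can
never extend a match past the recorded truth interval.

The fragment model is deliberately simple: a fragment is either spike-in
(uniform on the spike genome), signal (Gaussian around a random truth
site) or background (uniform on the sample genome). Tn5 insertion bias and
nucleosome structure are out of scope. "Mung-bean mode" multiplies the
truth-site draw probability by a residual factor, emulating the signal
depletion caused by single-strand-specific nuclease pretreatment.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .intervals import FragmentSet, GenomicInterval
from .io import (
    SequenceRecord,
    atomic_open,
    write_fasta,
    write_fastq,
    write_bed,
    write_fragment_bed,
)
from .scan import (
    INTERSTRAND_COMPOSITIONS,
    PQSMatch,
    reverse_complement,
)

GUARD_BP = 15  # A/T pad flanking each implant; > max loop length (12)
SITE_CLASSES = ("canonical", "extended", "two_tetrad", "interstrand")


@dataclass
class SimConfig:
    """Parameters of one simulated study.

    Defaults mirror the intended study conditions: three 100 kb sample
    chromosomes plus one 20 kb spike chromosome in its own namespace, 40%
    GC, 25 implanted sites per motif class (the interstrand sites cycle
    through the 8 compositions), 20-fold signal enrichment at truth sites,
    fragment lengths ~N(150, 30) truncated to [30, 1000], 100 000 fragments
    per library, 5% spike-in, and a mung-bean residual signal factor of
    0.15.
    """

    seed: int = 0
    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {
            "chr1": 100_000,
            "chr2": 100_000,
            "chr3": 100_000,
        }
    )
    spike_chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"dm_chr1": 20_000}
    )
    gc_content: float = 0.4
    n_sites_per_class: int = 25
    enrichment_fold: float = 20.0
    frag_len_mean: float = 150.0
    frag_len_sd: float = 30.0
    library_size: int = 100_000
    spike_fraction: float = 0.05
    mung_bean_factor: float = 0.15

    def __post_init__(self) -> None:
        if not (0 <= self.spike_fraction < 1):
            raise ValueError("spike_fraction must be in [0, 1)")
        if self.enrichment_fold < 1:
            raise ValueError("enrichment_fold must be >= 1")
        for name, size in {**self.chrom_sizes, **self.spike_chrom_sizes}.items():
            if size <= 0:
                raise ValueError(f"chromosome {name!r} must have positive size")
        if self.library_size <= 0 or self.n_sites_per_class < 0:
            raise ValueError("library_size must be > 0 and site count >= 0")

    def sample_genome_size(self) -> int:
        return sum(self.chrom_sizes.values())


# ---------------------------------------------------------------------------
# background sequence with G/C-run suppression
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _background_sequence(
    size: int, gc_content: float, rng: np.random.Generator
) -> list[str]:
    """i.i.d. background at the requested GC, with no run of >=3 G or C.

    Single left-to-right pass with rejection resampling: a draw that would
    complete a GGG/CCC run is redrawn from the remaining bases.
    """
    p = np.array(
        [
            (1 - gc_content) / 2,
            gc_content / 2,
            gc_content / 2,
            (1 - gc_content) / 2,
        ]
    )  # A, C, G, T
    draws = rng.choice(4, size=size, p=p)
    seq = [""] * size
    for i in range(size):
        base = _BASES[draws[i]]
        if i >= 2 and base in "GC" and seq[i - 1] == base and seq[i - 2] == base:
            others = [b for b in "ACGT" if b != base]
            weights = np.array([p["ACGT".index(b)] for b in others])
            base = rng.choice(others, p=weights / weights.sum())
        seq[i] = base
    return seq


# ---------------------------------------------------------------------------
# implant construction
# ---------------------------------------------------------------------------


def _loops(rng, n, lo, hi) -> list[str]:
    """Loop sequences from {A, T} so implants never gain extra G/C runs."""
    return [
        "".join(rng.choice(["A", "T"], size=int(rng.integers(lo, hi + 1))))
        for _ in range(n)
    ]


def _build_site(
    class_id: str, composition: str | None, rng: np.random.Generator
) -> tuple[str, str]:
    """One exact motif instance; returns (plus-strand sequence, strand).

    Intra-strand instances are implanted on a random strand (the minus
    version is the reverse complement); mixed interstrand compositions are
    unstranded. Extended instances always carry at least one loop longer
    than 7 nt so they are not also canonical hits.
    """
    if class_id == "canonical":
        loops = _loops(rng, 3, 1, 7)
        seq = "GGG" + "".join(l + "GGG" for l in loops)
        strand = str(rng.choice(["+", "-"]))
    elif class_id == "extended":
        loops = _loops(rng, 3, 1, 12)
        loops[int(rng.integers(0, 3))] = "".join(
            rng.choice(["A", "T"], size=int(rng.integers(8, 13)))
        )
        seq = "GGG" + "".join(l + "GGG" for l in loops)
        strand = str(rng.choice(["+", "-"]))
    elif class_id == "two_tetrad":
        loops = _loops(rng, 3, 1, 12)
        seq = "GG" + "".join(l + "GG" for l in loops)
        strand = str(rng.choice(["+", "-"]))
    elif class_id == "interstrand":
        assert composition is not None
        loops = _loops(rng, 3, 1, 7)
        runs = ["GGG" if c == "A" else "CCC" for c in composition]
        seq = runs[0] + "".join(l + r for l, r in zip(loops, runs[1:]))
        strand = "+" if composition == "AAAA" else "."
    else:
        raise ValueError(f"unknown site class {class_id!r}")
    if strand == "-":
        seq = reverse_complement(seq)
    return seq, strand


def make_genome(
    config: SimConfig,
) -> tuple[list[SequenceRecord], list[PQSMatch]]:
    """Synthetic genome plus ground-truth motif annotation.

    Sample chromosomes carry run-suppressed background with implanted exact
    motif instances of every class at uniformly spaced, non-overlapping
    positions; the spike chromosome is pure background in its own
    namespace. Deterministic for a fixed config seed. Raises when the
    genome is too small for the requested number of sites.
    """
    rng = np.random.default_rng(config.seed)

    site_plan: list[tuple[str, str | None]] = []
    for class_id in SITE_CLASSES:
        for i in range(config.n_sites_per_class):
            comp = (
                INTERSTRAND_COMPOSITIONS[i % len(INTERSTRAND_COMPOSITIONS)]
                if class_id == "interstrand"
                else None
            )
            site_plan.append((class_id, comp))
    order = rng.permutation(len(site_plan))
    site_plan = [site_plan[i] for i in order]

    # allocate sites to sample chromosomes proportionally to size
    chroms = list(config.chrom_sizes)
    total = config.sample_genome_size()
    alloc: dict[str, int] = {}
    placed = 0
    for k, chrom in enumerate(chroms):
        if k == len(chroms) - 1:
            alloc[chrom] = len(site_plan) - placed
        else:
            alloc[chrom] = int(
                round(len(site_plan) * config.chrom_sizes[chrom] / total)
            )
            placed += alloc[chrom]

    records: list[SequenceRecord] = []
    truth: list[PQSMatch] = []
    cursor = 0
    for chrom in chroms:
        size = config.chrom_sizes[chrom]
        seq = _background_sequence(size, config.gc_content, rng)
        n_here = alloc[chrom]
        plan_here = site_plan[cursor : cursor + n_here]
        cursor += n_here
        spacing = size // (n_here + 1) if n_here else size
        for j, (class_id, comp) in enumerate(plan_here):
            site_seq, strand = _build_site(class_id, comp, rng)
            start = (j + 1) * spacing
            end = start + len(site_seq)
            if spacing < len(site_seq) + 2 * GUARD_BP + 1 or end + GUARD_BP > size:
                raise ValueError(
                    f"{chrom} too small for {n_here} sites of this size"
                )
            pad_left = [
                str(b) for b in rng.choice(["A", "T"], size=GUARD_BP)
            ]
            pad_right = [
                str(b) for b in rng.choice(["A", "T"], size=GUARD_BP)
            ]
            seq[start - GUARD_BP : start] = pad_left
            seq[start:end] = list(site_seq)
            seq[end : end + GUARD_BP] = pad_right
            truth.append(
                PQSMatch(
                    chrom,
                    start,
                    end,
                    strand,
                    name=f"{class_id}:{comp or '.'}",
                    class_id=class_id,
                    composition=comp,
                    matched_seq=site_seq,
                )
            )
        records.append(SequenceRecord(chrom, "".join(seq)))

    for chrom, size in config.spike_chrom_sizes.items():
        records.append(
            SequenceRecord(
                chrom,
                "".join(_background_sequence(size, config.gc_content, rng)),
            )
        )
    truth.sort(key=lambda t: (t.chrom, t.start))
    return records, truth


# ---------------------------------------------------------------------------
# fragment library simulation
# ---------------------------------------------------------------------------


def signal_probability(config: SimConfig, mung_bean: bool = False) -> float:
    """Probability that a non-spike fragment is drawn at a truth site.

    Signal is drawn with probability proportional to the enrichment fold
    against one unit of background: p = E / (E + 1). Mung-bean mode
    multiplies this truth-site draw probability by the residual factor.
    """
    p = config.enrichment_fold / (config.enrichment_fold + 1.0)
    return p * config.mung_bean_factor if mung_bean else p


def simulate_fragments(
    truth: list[PQSMatch],
    config: SimConfig,
    mung_bean: bool = False,
    rng: np.random.Generator | None = None,
) -> FragmentSet:
    """One CUT&Tag-like fragment library.

    ``library_size`` fragments total: each is spike-in with probability
    ``spike_fraction`` (uniform on the spike genome); otherwise signal with
    probability p = E/(E+1) (centred on a uniformly chosen truth site with
    Gaussian offset whose sd is the fragment's own length) or uniform
    background on the sample genome. Lengths are N(mean, sd) clipped to
    [30, 1000]. Fragment order is the draw order, so libraries are
    reproducible for a fixed rng state.
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, 1])
    p_signal = signal_probability(config, mung_bean)
    if not truth and config.enrichment_fold > 1 and p_signal > 0:
        raise ValueError(
            "cannot simulate enrichment without truth sites; "
            "set enrichment_fold=1 for background-only libraries"
        )

    n = config.library_size
    lengths = np.clip(
        np.round(rng.normal(config.frag_len_mean, config.frag_len_sd, n)),
        30,
        1000,
    ).astype(np.int64)
    is_spike = rng.random(n) < config.spike_fraction
    is_signal = (~is_spike) & (rng.random(n) < p_signal)

    sample_chroms = list(config.chrom_sizes)
    sample_sizes = np.array([config.chrom_sizes[c] for c in sample_chroms])
    spike_chroms = list(config.spike_chrom_sizes)
    spike_sizes = np.array([config.spike_chrom_sizes[c] for c in spike_chroms])

    chrom_out = np.empty(n, dtype=object)
    start_out = np.zeros(n, dtype=np.int64)

    # spike: uniform over the spike genome
    idx = np.flatnonzero(is_spike)
    if len(idx) > 0:
        picks = rng.choice(
            len(spike_chroms), size=len(idx), p=spike_sizes / spike_sizes.sum()
        )
        for k, chrom in enumerate(spike_chroms):
            sel = idx[picks == k]
            size = spike_sizes[k]
            lens = np.minimum(lengths[sel], size)
            lengths[sel] = lens
            start_out[sel] = rng.integers(0, size - lens + 1)
            chrom_out[sel] = chrom

    # signal: Gaussian around a random truth-site centre
    idx = np.flatnonzero(is_signal)
    if len(idx) > 0:
        site_idx = rng.integers(0, len(truth), size=len(idx))
        centres = np.array([(t.start + t.end) // 2 for t in truth])[site_idx]
        site_chrom = np.array([t.chrom for t in truth], dtype=object)[site_idx]
        offsets = rng.normal(0.0, lengths[idx].astype(float))
        sizes = np.array(
            [config.chrom_sizes[c] for c in site_chrom], dtype=np.int64
        )
        lens = np.minimum(lengths[idx], sizes)
        lengths[idx] = lens
        starts = np.round(centres + offsets - lens / 2).astype(np.int64)
        start_out[idx] = np.clip(starts, 0, sizes - lens)
        chrom_out[idx] = site_chrom

    # background: uniform over the sample genome
    idx = np.flatnonzero(~is_spike & ~is_signal)
    if len(idx) > 0:
        picks = rng.choice(
            len(sample_chroms),
            size=len(idx),
            p=sample_sizes / sample_sizes.sum(),
        )
        for k, chrom in enumerate(sample_chroms):
            sel = idx[picks == k]
            size = sample_sizes[k]
            lens = np.minimum(lengths[sel], size)
            lengths[sel] = lens
            start_out[sel] = rng.integers(0, size - lens + 1)
            chrom_out[sel] = chrom

    fragments = [
        GenomicInterval(
            str(chrom_out[i]), int(start_out[i]), int(start_out[i] + lengths[i])
        )
        for i in range(n)
    ]
    labels = ["spike" if s else "sample" for s in is_spike]
    return FragmentSet(fragments, labels)


def fragment_sequences(
    fragments: FragmentSet, records: list[SequenceRecord]
) -> list[str]:
    """Fragment DNA sequences looked up from the genome."""
    genome = {r.name: r.sequence for r in records}
    return [genome[f.chrom][f.start : f.end] for f in fragments]


def simulate_read_library(
    n_reads: int,
    telomeric_fraction: float,
    read_length: int = 50,
    unit: str = "TTAGGG",
    seed: int = 0,
) -> tuple[list[str], float]:
    """A read library with a known proportion of telomeric-repeat reads.

    Telomeric reads are tandem copies of the unit at a random phase and
    orientation; the rest are uniform random sequence (redrawn in the
    unlikely event they contain a tandem repeat). Returns the shuffled
    reads and the exact truth fraction.
    """
    rng = np.random.default_rng(seed)
    n_tel = int(round(n_reads * telomeric_fraction))
    tandem = unit * (read_length // len(unit) + 2)
    reads: list[str] = []
    for _ in range(n_tel):
        phase = int(rng.integers(0, len(unit)))
        read = tandem[phase : phase + read_length]
        if rng.random() < 0.5:
            read = reverse_complement(read)
        reads.append(read)
    probe_f, probe_r = unit * 2, reverse_complement(unit) * 2
    for _ in range(n_reads - n_tel):
        while True:
            read = "".join(rng.choice(list("ACGT"), size=read_length))
            if probe_f not in read and probe_r not in read:
                break
        reads.append(read)
    order = rng.permutation(n_reads)
    return [reads[i] for i in order], n_tel / n_reads


# ---------------------------------------------------------------------------
# fixture bundle
# ---------------------------------------------------------------------------


def write_fixture_bundle(
    out_dir: str | Path,
    config: SimConfig,
    include_fastq: bool = False,
) -> dict[str, Path]:
    """Write a complete synthetic dataset to ``out_dir``.

    Files: genome.fa (sample chromosomes), spike.fa (spike chromosome),
    truth.bed, fragments_native.bed, fragments_mb.bed, chrom.sizes,
    config.json and optionally fragments.fastq — enough to run every
    pipeline step end-to-end. Byte-identical when regenerated with the same
    config.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records, truth = make_genome(config)
    sample_records = [r for r in records if r.name in config.chrom_sizes]
    spike_records = [r for r in records if r.name in config.spike_chrom_sizes]
    native = simulate_fragments(
        truth, config, rng=np.random.default_rng([config.seed, 1])
    )
    mung = simulate_fragments(
        truth,
        config,
        mung_bean=True,
        rng=np.random.default_rng([config.seed, 2]),
    )
    paths = {
        "genome": out / "genome.fa",
        "spike": out / "spike.fa",
        "truth": out / "truth.bed",
        "fragments_native": out / "fragments_native.bed",
        "fragments_mb": out / "fragments_mb.bed",
        "chrom_sizes": out / "chrom.sizes",
        "config": out / "config.json",
    }
    write_fasta(sample_records, paths["genome"])
    write_fasta(spike_records, paths["spike"])
    write_bed(truth, paths["truth"])
    write_fragment_bed(native, paths["fragments_native"])
    write_fragment_bed(mung, paths["fragments_mb"])
    with atomic_open(paths["chrom_sizes"]) as handle:
        for chrom, size in {
            **config.chrom_sizes,
            **config.spike_chrom_sizes,
        }.items():
            handle.write(f"{chrom}\t{size}\n")
    with atomic_open(paths["config"]) as handle:
        json.dump(asdict(config), handle, indent=2, sort_keys=True)
        handle.write("\n")
    if include_fastq:
        paths["fastq"] = out / "fragments.fastq"
        write_fastq(fragment_sequences(native, records), paths["fastq"])
    return paths
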
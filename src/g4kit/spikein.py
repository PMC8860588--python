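"""Quantitative spike-in scaling.

A constant amount of exogenous chromatin (e.g. Drosophila S2, ~5% of each
library) is carried through tagmentation; because that content is constant
across samples, the per-sample fragment count mapping to the spike genome
is inversely proportional to overall recovery, and tracks can be rescaled
so the spike totals agree. Factors are defined on deduplicated fragment
counts, not DNA mass.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .intervals import FragmentSet, GenomicInterval
from .tracks import BinnedTrack


@dataclass
class ScalingFactors:
    """Per-sample spike counts and scale factors relative to a reference.

    ``factors[s] = spike_counts[reference] / spike_counts[s]``; the
    reference's factor is exactly 1 and all factors are positive.
    """

    spike_counts: dict[str, int]
    reference: str
    factors: dict[str, float]


def split_by_genome(
    fragments: FragmentSet, spike_chrom_prefix: str = "dm_"
) -> tuple[FragmentSet, FragmentSet]:
    """Partition fragments into (sample, spike) by chromosome namespace.

    Spike chromosomes are identified by a distinguishing name prefix. The
    partition is exhaustive and disjoint. Raises when no fragment maps to
    the spike genome, since a scale factor would then be undefined.
    """
    sample: list[GenomicInterval] = []
    spike: list[GenomicInterval] = []
    for frag in fragments:
        (spike if frag.chrom.startswith(spike_chrom_prefix) else sample).append(
            frag
        )
    if not spike:
        raise ValueError(
            f"no fragments on spike chromosomes (prefix "
            f"{spike_chrom_prefix!r}); scale factor undefined"
        )
    return (
        FragmentSet(sample, ["sample"] * len(sample)),
        FragmentSet(spike, ["spike"] * len(spike)),
    )


def scale_factors(
    spike_counts: Mapping[str, int], reference: str | None = None
) -> ScalingFactors:
    """Spike-in scale factors: factor_s = count_reference / count_s.

    The reference defaults to the first sample in mapping order (relative
    scaling is all that is needed). Zero counts are an error.
    """
    if not spike_counts:
        raise ValueError("no spike counts given")
    if reference is None:
        reference = next(iter(spike_counts))
    if reference not in spike_counts:
        raise ValueError(f"reference sample {reference!r} not among counts")
    for sample, count in spike_counts.items():
        if count <= 0:
            raise ValueError(f"sample {sample!r} has non-positive spike count")
    ref_count = spike_counts[reference]
    return ScalingFactors(
        spike_counts=dict(spike_counts),
        reference=reference,
        factors={s: ref_count / c for s, c in spike_counts.items()},
    )


def apply_scaling(track: BinnedTrack, factor: float) -> BinnedTrack:
    """Multiply every bin by the spike-in factor; norm label becomes 'spike'."""
    if factor <= 0:
        raise ValueError("scale factor must be > 0")
    return track.scaled(factor, norm="spike")
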
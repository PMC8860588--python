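"""Fixed-bin per-chromosome signal tracks."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

NORMS = ("raw", "RPGC", "spike", "occupancy")


@dataclass
class BinnedTrack:
    """Per-chromosome signal in fixed-size bins.

    Each chromosome's vector has ``ceil(chrom_size / bin_size)`` entries; the
    last bin may extend past the chromosome end and is always divided by the
    full ``bin_size`` (matching genome-browser bin conventions). ``norm``
    records how the values were scaled: ``raw`` (mean per-bp fragment depth),
    ``RPGC`` (1x genome coverage), ``spike`` (spike-in scaled) or
    ``occupancy`` (fraction of bin bp covered, in [0, 1]).
    """

    bin_size: int
    chrom_sizes: dict[str, int]
    data: dict[str, np.ndarray] = field(default_factory=dict)
    norm: str = "raw"

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        if self.norm not in NORMS:
            raise ValueError(f"unknown normalization {self.norm!r}")
        for chrom, size in self.chrom_sizes.items():
            n_bins = -(-size // self.bin_size)
            if chrom not in self.data:
                self.data[chrom] = np.zeros(n_bins)
            elif len(self.data[chrom]) != n_bins:
                raise ValueError(
                    f"{chrom}: expected {n_bins} bins, got {len(self.data[chrom])}"
                )

    def n_bins(self) -> int:
        return sum(len(v) for v in self.data.values())

    def concatenated(self) -> np.ndarray:
        """All bins in sorted chromosome order as one vector."""
        return np.concatenate(
            [self.data[c] for c in sorted(self.data)]
        ) if self.data else np.zeros(0)

    def genome_mean(self) -> float:
        """Mean bin value over the whole track."""
        return float(self.concatenated().mean())

    def scaled(self, factor: float, norm: str | None = None) -> "BinnedTrack":
        """A copy with every bin multiplied by ``factor``."""
        return BinnedTrack(
            bin_size=self.bin_size,
            chrom_sizes=dict(self.chrom_sizes),
            data={c: v * factor for c, v in self.data.items()},
            norm=norm or self.norm,
        )
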
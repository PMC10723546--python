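"""Uniform-width binned genome tracks and breakpoint binning."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..cohort_io.model import InvalidInputError

DEFAULT_BIN_WIDTH = 100_000


@dataclass
class BinnedTrack:
    """Per-chromosome arrays of values on a uniform bin grid (0-based bins)."""

    bin_width: int
    values: dict = field(default_factory=dict)  # chrom -> np.ndarray

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise InvalidInputError("bin width must be positive")
        self.values = {c: np.asarray(v, dtype=float) for c, v in self.values.items()}

    @property
    def n_bins(self) -> int:
        return int(sum(v.size for v in self.values.values()))

    @property
    def total(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))

    def concat(self) -> np.ndarray:
        """All bin values in sorted-chromosome order."""
        return np.concatenate([self.values[c] for c in sorted(self.values)])

    def like(self, flat: np.ndarray) -> "BinnedTrack":
        """Rebuild a track from a flat vector in sorted-chromosome order."""
        out, offset = {}, 0
        for chrom in sorted(self.values):
            n = self.values[chrom].size
            out[chrom] = np.asarray(flat[offset : offset + n], dtype=float)
            offset += n
        return BinnedTrack(self.bin_width, out)

    def bin_interval(self, chrom: str, i: int) -> tuple:
        """0-based half-open genomic interval of bin i."""
        return (chrom, i * self.bin_width, (i + 1) * self.bin_width)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for chrom in sorted(self.values):
            for i, v in enumerate(self.values[chrom]):
                rows.append((chrom, i * self.bin_width, (i + 1) * self.bin_width, v))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])

    def same_grid(self, other: "BinnedTrack") -> bool:
        return (
            self.bin_width == other.bin_width
            and set(self.values) == set(other.values)
            and all(self.values[c].size == other.values[c].size for c in self.values)
        )


def empty_track(genome, bin_width: int = DEFAULT_BIN_WIDTH) -> BinnedTrack:
    """All-zero track tiling a genome of (chrom, length, ...) entries."""
    values = {}
    for entry in genome:
        chrom, length = entry[0], entry[1]
        n = int(np.ceil(length / bin_width))
        values[chrom] = np.zeros(n)
    return BinnedTrack(bin_width, values)


def bin_breakpoints(svs, genome, bin_width: int = DEFAULT_BIN_WIDTH) -> BinnedTrack:
    """Count SV breakpoint ends per bin; every SV contributes both ends."""
    track = empty_track(genome, bin_width)
    lengths = {entry[0]: entry[1] for entry in genome}
    for sv in svs:
        for chrom, pos in sv.breakends:
            if chrom not in track.values:
                raise InvalidInputError(f"breakpoint chromosome {chrom} not in genome")
            if not (1 <= pos <= lengths[chrom]):
                raise InvalidInputError(
                    f"breakpoint {chrom}:{pos} outside chromosome length {lengths[chrom]}"
                )
            track.values[chrom][(pos - 1) // bin_width] += 1
    return track
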
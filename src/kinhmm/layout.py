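"""Genome window grid.

Both HMMs operate on large fixed-width genomic windows (default 10 Mb).
Windows are 0-based half-open on physical coordinates and tile each
chromosome; the last window of a chromosome may be shorter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_WINDOW_SIZE = 10_000_000


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome table plus the derived window grid.

    Attributes
    ----------
    chromosomes
        Ordered ``(name, length_bp)`` tuples.
    window_size
        Window width in bp.
    """

    chromosomes: tuple[tuple[str, int], ...]
    window_size: int = DEFAULT_WINDOW_SIZE
    # derived, filled in __post_init__
    window_chrom: np.ndarray = field(init=False, repr=False, compare=False)
    window_start: np.ndarray = field(init=False, repr=False, compare=False)
    window_end: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("empty chromosome table")
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        chroms, starts, ends = [], [], []
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")
            edges = np.arange(0, length, self.window_size, dtype=np.int64)
            chroms.extend([name] * len(edges))
            starts.append(edges)
            ends.append(np.minimum(edges + self.window_size, length))
        object.__setattr__(self, "window_chrom", np.array(chroms, dtype=object))
        object.__setattr__(self, "window_start", np.concatenate(starts))
        object.__setattr__(self, "window_end", np.concatenate(ends))

    @property
    def L(self) -> int:
        """Total number of windows."""
        return len(self.window_start)

    @property
    def chrom_names(self) -> list[str]:
        return [c for c, _ in self.chromosomes]

    def chrom_length(self, name: str) -> int:
        for c, length in self.chromosomes:
            if c == name:
                return length
        raise KeyError(name)

    def n_windows(self, name: str) -> int:
        length = self.chrom_length(name)
        return -(-length // self.window_size)

    def chrom_slices(self) -> list[slice]:
        """Per-chromosome slices into the window axis, in chromosome order.

        HMM chains restart (with the stationary distribution) at each
        chromosome start, so every consumer iterates over these slices.
        """
        out, offset = [], 0
        for name, _ in self.chromosomes:
            n = self.n_windows(name)
            out.append(slice(offset, offset + n))
            offset += n
        return out

    def window_index(self, chrom: str, pos0: np.ndarray) -> np.ndarray:
        """Window index for 0-based positions on ``chrom``."""
        offset = 0
        for name, _ in self.chromosomes:
            if name == chrom:
                return offset + np.asarray(pos0, dtype=np.int64) // self.window_size
            offset += self.n_windows(name)
        raise KeyError(f"unknown chromosome {chrom!r}")

    def window_centers(self) -> np.ndarray:
        """Central bp (0-based) of every window."""
        return (self.window_start + self.window_end) // 2


def build_window_grid(
    chromosomes: list[tuple[str, int]], window_size: int = DEFAULT_WINDOW_SIZE
) -> GenomeLayout:
    """Tile chromosomes with half-open windows of ``window_size`` bp."""
    return GenomeLayout(tuple((str(c), int(l)) for c, l in chromosomes), int(window_size))
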
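"""Genome coordinate system and window grids.

All coordinates are 0-based, half-open, in base pairs. A genome is an
ordered collection of chromosomes; a :class:`WindowGrid` tiles each
chromosome with fixed-size windows (the last window on a chromosome may
be shorter).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Genome",
    "WindowGrid",
    "build_genome",
    "default_maize_genome",
    "make_window_grid",
    "read_genome",
    "write_genome",
    "MAIZE_CHROM_LENGTHS",
]

# Rounded lengths (bp) of the ten maize chromosomes, B73-like assembly,
# ~2,056 Mb total. Overridable: any (id, length) table builds a Genome.
MAIZE_CHROM_LENGTHS: tuple[tuple[str, int], ...] = (
    ("1", 301_000_000),
    ("2", 237_000_000),
    ("3", 232_000_000),
    ("4", 242_000_000),
    ("5", 217_000_000),
    ("6", 169_000_000),
    ("7", 176_000_000),
    ("8", 175_000_000),
    ("9", 157_000_000),
    ("10", 150_000_000),
)


@dataclass(frozen=True)
class Genome:
    """Ordered chromosome ids and physical lengths in bp."""

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("genome must contain at least one chromosome")
        ids = [c for c, _ in self.chromosomes]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate chromosome id(s): {dupes}")
        for cid, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {cid!r} has non-positive length {length}")

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.chromosomes)

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.chromosomes)

    def length_of(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def __len__(self) -> int:
        return len(self.chromosomes)


def build_genome(spec: Iterable[tuple[str, float]]) -> Genome:
    """Build a :class:`Genome` from (id, length_bp) pairs.

    Lengths may be given as floats (e.g. ``300e6``) and are truncated to
    integer bp.
    """
    chroms = tuple((str(cid), int(length)) for cid, length in spec)
    return Genome(chroms)


def default_maize_genome() -> Genome:
    """The bundled ten-chromosome maize genome (~2,056 Mb)."""
    return Genome(MAIZE_CHROM_LENGTHS)


@dataclass(frozen=True)
class WindowGrid:
    """Fixed-size tiling of every chromosome of a genome.

    ``starts[chrom]`` holds window start positions; window *i* spans
    ``[starts[i], min(starts[i] + window_size, length))``.
    """

    genome: Genome
    window_size: int

    def __post_init__(self) -> None:
        if self.window_size <= 0:
            raise ValueError(f"window_size must be positive, got {self.window_size}")

    def n_windows(self, chrom: str) -> int:
        return math.ceil(self.genome.length_of(chrom) / self.window_size)

    @property
    def total_windows(self) -> int:
        return sum(self.n_windows(c) for c in self.genome.ids)

    def starts(self, chrom: str) -> np.ndarray:
        return np.arange(self.n_windows(chrom), dtype=np.int64) * self.window_size

    def ends(self, chrom: str) -> np.ndarray:
        ends = self.starts(chrom) + self.window_size
        ends[-1] = min(ends[-1], self.genome.length_of(chrom))
        return ends

    def midpoints(self, chrom: str) -> np.ndarray:
        """Window midpoints (bp, float) — used as marker positions."""
        return (self.starts(chrom) + self.ends(chrom)) / 2.0

    def window_of(self, chrom: str, pos: np.ndarray | float) -> np.ndarray:
        """Index of the window containing each position."""
        idx = np.asarray(pos, dtype=np.int64) // self.window_size
        return idx

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom in self.genome.ids:
            s, e = self.starts(chrom), self.ends(chrom)
            rows.append(pd.DataFrame({"chrom": chrom, "start": s, "end": e}))
        return pd.concat(rows, ignore_index=True)


def make_window_grid(genome: Genome, window_size: int) -> WindowGrid:
    """Tile every chromosome of ``genome`` with ``window_size``-bp windows."""
    return WindowGrid(genome, int(window_size))


def read_genome(path) -> Genome:
    """Read a genome from a two-column TSV (chrom, length_bp), no header."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"],
                     dtype={"chrom": str})
    return build_genome(zip(df["chrom"], df["length"]))


def write_genome(genome: Genome, path) -> None:
    pd.DataFrame(genome.chromosomes, columns=["chrom", "length"]).to_csv(
        path, sep="\t", header=False, index=False
    )
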
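"""Summary statistics of simulated populations.

Two fragment-length readouts coexist deliberately:

* the per-line value, total physical genome length divided by the
  line's breakpoint count (hundreds of Mb for typical counts); and
* the pooled bin-map value, where every line's breakpoints are snapped
  to window starts, pooled across the population, and the lengths of
  the resulting recombination bins (blocks no line recombines in) are
  summarized — this is the readout that lives on the sub-Mb scale.

Both are reported, clearly labelled.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import Genome, WindowGrid
from .meiosis import Haplotype, Individual
from .schemes import Population, consensus_mosaic

__all__ = [
    "SummaryStats",
    "BinMap",
    "count_breakpoints",
    "per_line_fragment_length",
    "build_bin_map",
    "pooled_fragment_stats",
    "summarize",
]


def count_breakpoints(line: Individual | Haplotype) -> int:
    """Number of recombination events of a line.

    Sum over chromosomes of the line's observable founder switches
    (segments − 1 after invisible-junction merging) on its consensus
    mosaic.
    """
    mosaic = line if isinstance(line, Haplotype) else consensus_mosaic(line)
    return mosaic.n_junctions()


def per_line_fragment_length(line: Individual | Haplotype,
                             genome: Genome) -> float:
    """Mean recombination fragment length of one line, in Mb.

    Total physical genome length divided by the line's breakpoint
    count; NaN for lines with no breakpoints.
    """
    n = count_breakpoints(line)
    if n == 0:
        return math.nan
    return genome.total_length / n / 1e6


@dataclass(frozen=True)
class BinMap:
    """Population-pooled recombination bins.

    ``boundaries[chrom]`` holds the sorted distinct window-snapped
    breakpoint positions; bins are the segments between consecutive
    boundaries and the chromosome ends.
    """

    genome: Genome
    window_size: int
    boundaries: dict[str, np.ndarray]

    def bins(self, chrom: str) -> np.ndarray:
        """(start, end) array of bins on one chromosome."""
        L = self.genome.length_of(chrom)
        edges = np.concatenate([[0], self.boundaries[chrom], [L]])
        return np.column_stack([edges[:-1], edges[1:]])

    @property
    def n_bins(self) -> int:
        return sum(len(self.boundaries[c]) + 1 for c in self.genome.ids)

    def bin_lengths_mb(self) -> np.ndarray:
        out = [np.diff(np.concatenate([[0], self.boundaries[c],
                                       [self.genome.length_of(c)]]))
               for c in self.genome.ids]
        return np.concatenate(out) / 1e6

    def to_frame(self) -> pd.DataFrame:
        rows = [pd.DataFrame({"chrom": c,
                              "start": self.bins(c)[:, 0].astype(np.int64),
                              "end": self.bins(c)[:, 1].astype(np.int64)})
                for c in self.genome.ids]
        return pd.concat(rows, ignore_index=True)


def build_bin_map(pop: Population, grid: WindowGrid) -> BinMap:
    """Pool window-resolved breakpoints of all lines into a bin map.

    Each breakpoint is snapped to the start of its containing window;
    distinct snapped positions (excluding 0) delimit the bins.
    """
    ws = grid.window_size
    boundaries: dict[str, np.ndarray] = {}
    for chrom in pop.genome.ids:
        snapped: set[int] = set()
        for mosaic in pop.mosaics():
            for start, _end, _label in mosaic.segments[chrom][1:]:
                snapped.add(int(start // ws) * ws)
        snapped.discard(0)
        boundaries[chrom] = np.array(sorted(snapped), dtype=np.int64)
    return BinMap(pop.genome, ws, boundaries)


def pooled_fragment_stats(binmap: BinMap) -> tuple[float, float, float]:
    """(mean, median, sample sd) of pooled bin lengths, in Mb."""
    lengths = binmap.bin_lengths_mb()
    if lengths.size == 0:
        raise ValueError("empty bin map")
    sd = float(np.std(lengths, ddof=1)) if lengths.size > 1 else 0.0
    return float(np.mean(lengths)), float(np.median(lengths)), sd


@dataclass(frozen=True)
class SummaryStats:
    """All per-population summary statistics, JSON-serializable."""

    scheme: str
    n_lines: int
    seed: int
    events: tuple[int, ...]                # per-line breakpoint counts
    mean_events: float
    sd_events: float
    median_events: float
    eq_fragment_mb: tuple[float, ...]      # per-line genome-length / events
    eq_mean_fragment_mb: float
    bin_count: int
    pooled_mean_mb: float
    pooled_median_mb: float
    pooled_sd_mb: float

    def to_dict(self) -> dict:
        d = {
            "scheme": self.scheme,
            "n_lines": self.n_lines,
            "seed": self.seed,
            "mean_events": round(self.mean_events, 6),
            "sd_events": round(self.sd_events, 6),
            "median_events": round(self.median_events, 6),
            "eq2_mean_fragment_mb": round(self.eq_mean_fragment_mb, 6),
            "bin_count": self.bin_count,
            "pooled_mean_mb": round(self.pooled_mean_mb, 6),
            "pooled_median_mb": round(self.pooled_median_mb, 6),
            "pooled_sd_mb": round(self.pooled_sd_mb, 6),
        }
        return d

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def summarize(pop: Population, grid: WindowGrid) -> SummaryStats:
    """Assemble event counts, fragment lengths and bin statistics."""
    if len(pop) == 0:
        raise ValueError("empty population")
    events = np.array([count_breakpoints(m) for m in pop.mosaics()])
    frags = np.array([pop.genome.total_length / n / 1e6 if n else math.nan
                      for n in events])
    binmap = build_bin_map(pop, grid)
    pooled_mean, pooled_median, pooled_sd = pooled_fragment_stats(binmap)
    return SummaryStats(
        scheme=pop.spec.label,
        n_lines=len(pop),
        seed=pop.spec.seed,
        events=tuple(int(e) for e in events),
        mean_events=float(events.mean()),
        sd_events=float(events.std(ddof=1)) if len(events) > 1 else 0.0,
        median_events=float(np.median(events)),
        eq_fragment_mb=tuple(float(f) for f in frags),
        eq_mean_fragment_mb=float(np.nanmean(frags)) if np.any(~np.isnan(frags))
        else math.nan,
        bin_count=binmap.n_bins,
        pooled_mean_mb=pooled_mean,
        pooled_median_mb=pooled_median,
        pooled_sd_mb=pooled_sd,
    )
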
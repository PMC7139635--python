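"""Window-level recombination-rate maps.

A :class:`RecombinationMap` attaches a nonnegative cM-like weight to
every window of a :class:`~recsim.genome.WindowGrid` and, per
chromosome, the normalized crossover-placement probabilities
``prob_w = rate_w / sum(rate on that chromosome)``.

The absolute cM scale of the weights cancels in this normalization; only
the relative landscape matters for crossover placement.

A synthetic generator emulates the empirical maize intermated-population
landscape: right-skewed window rates in [0, 12.1] cM per 125 kb with
mean 3.48 cM, a fraction of recombination-dead windows, and suppressed
rates around the centromere.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .genome import Genome, WindowGrid, build_genome, make_window_grid

__all__ = [
    "RecombinationMap",
    "SyntheticMapParams",
    "generate_synthetic_map",
    "normalize_map",
    "read_map",
    "write_map",
]


@dataclass(frozen=True)
class RecombinationMap:
    """Per-window rates and per-chromosome crossover-placement probabilities."""

    grid: WindowGrid
    rates: dict[str, np.ndarray]  # chrom -> per-window weight, >= 0
    probs: dict[str, np.ndarray] = field(default=None)  # chrom -> placement prob
    _cdfs: dict[str, np.ndarray] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        for chrom in self.grid.genome.ids:
            r = np.asarray(self.rates[chrom], dtype=float)
            if r.shape != (self.grid.n_windows(chrom),):
                raise ValueError(
                    f"chromosome {chrom!r}: expected {self.grid.n_windows(chrom)} "
                    f"rates, got {r.shape}"
                )
            if np.any(r < 0):
                raise ValueError(f"negative rate on chromosome {chrom!r}")
            object.__setattr__(self, "rates", {**self.rates, chrom: r})
        if self.probs is None:
            object.__setattr__(self, "probs", _normalize(self.rates, self.grid))
        if self._cdfs is None:
            object.__setattr__(
                self, "_cdfs", {c: np.cumsum(p) for c, p in self.probs.items()}
            )

    @property
    def mean_rate(self) -> float:
        """Mean window rate over the whole genome."""
        return float(np.mean(np.concatenate(list(self.rates.values()))))

    @property
    def max_rate(self) -> float:
        return float(np.max(np.concatenate(list(self.rates.values()))))

    def sample_window(self, chrom: str, rng: np.random.Generator, size=None):
        """Draw window indices with probability ``prob_w`` (inverse-CDF)."""
        u = rng.random(size)
        return np.searchsorted(self._cdfs[chrom], u, side="right")

    def to_frame(self) -> pd.DataFrame:
        df = self.grid.to_frame()
        df["rate"] = np.concatenate([self.rates[c] for c in self.grid.genome.ids])
        return df


def _normalize(rates: Mapping[str, np.ndarray], grid: WindowGrid) -> dict[str, np.ndarray]:
    probs = {}
    for chrom in grid.genome.ids:
        total = rates[chrom].sum()
        if total <= 0:
            raise ValueError(
                f"chromosome {chrom!r} has zero total recombination rate; "
                "cannot normalize placement probabilities"
            )
        probs[chrom] = rates[chrom] / total
    return probs


def normalize_map(rec_map: RecombinationMap) -> RecombinationMap:
    """Recompute placement probabilities from the rates (idempotent)."""
    return RecombinationMap(rec_map.grid, dict(rec_map.rates))


@dataclass(frozen=True)
class SyntheticMapParams:
    """Parameters of the synthetic intermated-maize-like rate landscape.

    target_mean
        Genome-wide mean window rate after calibration (cM per window);
        default 3.48, the empirical 125 kb mean.
    max_rate
        Hard cap on any window rate (cM); default 12.1.
    zero_fraction
        Proportion of windows forced to rate 0 (recombination deserts).
    centromere_span
        Fraction of each chromosome, centred on the centromere, whose
        rates are multiplied by ``suppression_factor``.
    suppression_factor
        Multiplier in (0, 1] applied to centromeric windows.
    shape
        Gamma shape of the raw draw; < 1 gives the strong right skew of
        real hotspot landscapes.
    centromere_pos
        Centromere location as a fraction of chromosome length.
    """

    target_mean: float = 3.48
    max_rate: float = 12.1
    zero_fraction: float = 0.10
    centromere_span: float = 0.20
    suppression_factor: float = 0.10
    shape: float = 0.7
    centromere_pos: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.target_mean <= self.max_rate):
            raise ValueError("target_mean must lie in (0, max_rate]")
        if not (0 <= self.zero_fraction < 1):
            raise ValueError("zero_fraction must lie in [0, 1)")
        if not (0 < self.suppression_factor <= 1):
            raise ValueError("suppression_factor must lie in (0, 1]")
        if self.shape <= 0:
            raise ValueError("shape must be positive")


def generate_synthetic_map(
    grid: WindowGrid,
    params: SyntheticMapParams = SyntheticMapParams(),
    seed: int | np.random.SeedSequence | None = 0,
) -> RecombinationMap:
    """Generate a synthetic rate landscape on ``grid``.

    Window rates are drawn from a gamma distribution, a random
    ``zero_fraction`` of windows is zeroed, centromeric windows are
    suppressed, and the whole landscape is rescaled so that, after
    capping at ``max_rate``, the genome-wide mean equals ``target_mean``
    exactly. Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    raw: dict[str, np.ndarray] = {}
    for chrom in grid.genome.ids:
        n = grid.n_windows(chrom)
        r = rng.gamma(params.shape, 1.0, size=n)
        if params.zero_fraction > 0:
            r[rng.random(n) < params.zero_fraction] = 0.0
        # suppress the centromeric span
        length = grid.genome.length_of(chrom)
        centro = params.centromere_pos * length
        half = 0.5 * params.centromere_span * length
        mid = grid.midpoints(chrom)
        r[np.abs(mid - centro) <= half] *= params.suppression_factor
        raw[chrom] = r

    flat = np.concatenate([raw[c] for c in grid.genome.ids])
    if not np.any(flat > 0):
        raise ValueError("all synthetic rates are zero; cannot rescale to target mean")

    scale = _solve_scale(flat, params.target_mean, params.max_rate)
    rates = {c: np.minimum(r * scale, params.max_rate) for c, r in raw.items()}
    return RecombinationMap(grid, rates)


def _solve_scale(raw: np.ndarray, target_mean: float, max_rate: float) -> float:
    """Scale factor s with mean(min(s * raw, max_rate)) == target_mean.

    The capped mean is continuous and nondecreasing in s, so the root is
    found by bracketing + brentq. Raises if the target is unreachable
    (too few positive windows for the cap to allow the target mean).
    """

    def capped_mean(s: float) -> float:
        return float(np.mean(np.minimum(s * raw, max_rate)))

    attainable = float(np.mean(np.where(raw > 0, max_rate, 0.0)))
    if target_mean > attainable:
        raise ValueError(
            f"target mean {target_mean} unreachable: capped landscape can "
            f"reach at most {attainable:.4g}"
        )
    lo = target_mean / float(raw.mean())  # no-cap solution; capped_mean(lo) <= target
    hi = lo
    while capped_mean(hi) < target_mean:
        hi *= 2.0
    if hi == lo:
        return lo
    return brentq(lambda s: capped_mean(s) - target_mean, lo, hi, xtol=1e-12, rtol=1e-14)


def read_map(path) -> RecombinationMap:
    """Read a BED-like map (chrom, start, end, rate; TSV, no header).

    Windows must be sorted, non-overlapping and contiguous from 0 on
    each chromosome; all windows share one size except possibly the last
    per chromosome. The genome is inferred from the last window ends.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "rate"],
        dtype={"chrom": str},
    )
    if df.empty:
        raise ValueError(f"empty map file: {path}")
    if (df["rate"] < 0).any():
        bad = df.index[df["rate"] < 0][0]
        raise ValueError(f"negative rate at line {bad + 1}")
    if (df["start"] >= df["end"]).any():
        bad = df.index[df["start"] >= df["end"]][0]
        raise ValueError(f"window with start >= end at line {bad + 1}")

    window_size = int(df["end"].iloc[0] - df["start"].iloc[0])
    chrom_order = list(dict.fromkeys(df["chrom"]))
    lengths = []
    for chrom in chrom_order:
        sub = df[df["chrom"] == chrom]
        starts, ends = sub["start"].to_numpy(), sub["end"].to_numpy()
        if starts[0] != 0 or np.any(starts[1:] != ends[:-1]):
            raise ValueError(f"windows on chromosome {chrom!r} are overlapping, "
                             "out of order, or leave gaps")
        if np.any(ends[:-1] - starts[:-1] != window_size):
            raise ValueError(f"non-uniform window size on chromosome {chrom!r}")
        lengths.append((chrom, int(ends[-1])))
    genome = build_genome(lengths)
    grid = make_window_grid(genome, window_size)
    rates = {c: df.loc[df["chrom"] == c, "rate"].to_numpy(dtype=float)
             for c in chrom_order}
    return RecombinationMap(grid, rates)


def write_map(rec_map: RecombinationMap, path) -> None:
    """Write the map as BED-like TSV (chrom, start, end, rate), 6-decimal rates."""
    df = rec_map.to_frame()
    df["rate"] = df["rate"].map(lambda v: f"{v:.6f}")
    df.to_csv(path, sep="\t", header=False, index=False)
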
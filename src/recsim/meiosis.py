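"""Per-meiosis crossover sampling and gamete formation.

The engine is parameterized by two empirical quantities measured in real
doubled-haploid maize material:

* a per-chromosome crossover-*count* distribution over {0, 1, 2, 3}
  (the published rates 0.16/0.30/0.23/0.15 renormalized to sum to 1,
  giving a mean of ~1.44 crossovers per chromosome per meiosis); and
* a window-level crossover-*placement* probability landscape
  (:class:`~recsim.ratemap.RecombinationMap`).

Crossover interference is modelled as a hard rule: two crossovers on the
same chromosome in one meiosis must be >= ``min_separation`` bp apart
(default 10 Mb), enforced by rejection-resampling the positions while
keeping the sampled count fixed.

Gamete transmission is a random walk over the two parental haplotypes:
a fair coin picks the starting haplotype and every crossover position
switches strands. Junctions between segments of identical founder
origin are invisible and merged away.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .genome import Genome
from .ratemap import RecombinationMap

__all__ = [
    "CrossoverCountDistribution",
    "Haplotype",
    "Individual",
    "MeiosisParams",
    "InterferenceFallbackWarning",
    "RAW_COUNT_PROBS",
    "renormalize_count_dist",
    "sample_crossover_count",
    "sample_crossover_positions",
    "form_gamete",
    "merge_invisible_junctions",
]

# Empirical per-chromosome crossover-count rates measured in 2233 maize
# F1-DH lines; they sum to 0.84 and are renormalized before sampling.
RAW_COUNT_PROBS: tuple[float, ...] = (0.16, 0.30, 0.23, 0.15)


@dataclass(frozen=True)
class CrossoverCountDistribution:
    """Probabilities of 0..K crossovers per chromosome per meiosis."""

    support: np.ndarray
    p: np.ndarray

    def __post_init__(self) -> None:
        support = np.asarray(self.support, dtype=np.int64)
        p = np.asarray(self.p, dtype=float)
        if support.shape != p.shape or support.ndim != 1:
            raise ValueError("support and p must be 1-D arrays of equal length")
        if np.any(p < 0):
            raise ValueError("probabilities must be nonnegative")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"probabilities must sum to 1, got {p.sum()!r}")
        object.__setattr__(self, "support", support)
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "_cdf", np.cumsum(p))

    @property
    def mean(self) -> float:
        return float(np.dot(self.support, self.p))

    @classmethod
    def from_raw(cls, raw_p=RAW_COUNT_PROBS) -> "CrossoverCountDistribution":
        return renormalize_count_dist(raw_p)

    def sample(self, rng: np.random.Generator, size=None):
        u = rng.random(size)
        idx = np.searchsorted(self._cdf, u, side="right")
        return self.support[idx]


def renormalize_count_dist(raw_p) -> CrossoverCountDistribution:
    """Renormalize raw count rates over support {0..len-1} to sum to 1."""
    raw = np.asarray(raw_p, dtype=float)
    if np.any(raw < 0):
        raise ValueError("raw probabilities must be nonnegative")
    total = raw.sum()
    if total <= 0:
        raise ValueError("raw probabilities sum to zero")
    if total > 1 + 1e-9:
        raise ValueError(f"raw probabilities sum to {total} > 1")
    return CrossoverCountDistribution(np.arange(len(raw)), raw / total)


def sample_crossover_count(dist: CrossoverCountDistribution,
                           rng: np.random.Generator) -> int:
    """Draw one crossover count from ``dist``."""
    return int(dist.sample(rng))


class InterferenceFallbackWarning(UserWarning):
    """Raised when min-separation rejection sampling exhausts its budget."""


@dataclass(frozen=True)
class MeiosisParams:
    """Everything one meiosis needs: counts, placement map, interference."""

    count_dist: CrossoverCountDistribution
    rec_map: RecombinationMap
    min_separation: int = 10_000_000  # bp; hard crossover-interference rule
    max_resample: int = 1000

    def __post_init__(self) -> None:
        if self.min_separation < 0:
            raise ValueError("min_separation must be >= 0")

    @property
    def genome(self) -> Genome:
        return self.rec_map.grid.genome


def sample_crossover_positions(
    chrom: str,
    rec_map: RecombinationMap,
    k: int,
    min_separation: int,
    rng: np.random.Generator,
    max_resample: int = 1000,
) -> np.ndarray:
    """Sample ``k`` sorted crossover positions (bp) on one chromosome.

    Each position picks a window with probability ``prob_w`` and a
    uniform offset inside it. The whole k-set is rejected and redrawn
    until all pairwise distances are >= ``min_separation``; the count k
    is never altered. If no valid set is found in ``max_resample``
    attempts (geometrically impossible separations), the best-spread
    sample seen is returned with an :class:`InterferenceFallbackWarning`.
    """
    if k <= 0:
        return np.empty(0, dtype=float)
    grid = rec_map.grid
    starts = grid.starts(chrom)
    ends = grid.ends(chrom)

    def draw() -> np.ndarray:
        w = rec_map.sample_window(chrom, rng, size=k)
        pos = starts[w] + rng.random(k) * (ends[w] - starts[w])
        pos.sort()
        return pos

    if k == 1:
        return draw()

    best, best_gap = None, -1.0
    for _ in range(max_resample):
        pos = draw()
        gap = float(np.min(np.diff(pos)))
        if gap >= min_separation:
            return pos
        if gap > best_gap:
            best, best_gap = pos, gap
    warnings.warn(
        f"chromosome {chrom}: could not place {k} crossovers >= "
        f"{min_separation} bp apart in {max_resample} attempts; using the "
        f"best-spread sample (min gap {best_gap:.0f} bp)",
        InterferenceFallbackWarning,
        stacklevel=2,
    )
    return best


@dataclass(frozen=True)
class Haplotype:
    """Founder-labelled segment mosaic covering every chromosome.

    ``segments[chrom]`` is an ordered list of ``(start, end, founder)``
    tuples that tile ``[0, length)``; adjacent segments always carry
    distinct founder labels (invisible junctions are merged on
    construction).
    """

    genome: Genome
    segments: dict[str, list[tuple[float, float, int]]]

    def __post_init__(self) -> None:
        merged = {c: _merge_segments(s) for c, s in self.segments.items()}
        object.__setattr__(self, "segments", merged)

    @classmethod
    def pure(cls, genome: Genome, founder: int) -> "Haplotype":
        return cls(genome, {c: [(0.0, float(L), founder)]
                            for c, L in genome.chromosomes})

    def n_junctions(self, chrom: str | None = None) -> int:
        """Observable founder-switch points (segments − 1 per chromosome)."""
        if chrom is not None:
            return len(self.segments[chrom]) - 1
        return sum(len(s) - 1 for s in self.segments.values())

    def founder_at(self, chrom: str, pos: float) -> int:
        for start, end, label in self.segments[chrom]:
            if start <= pos < end:
                return label
        raise ValueError(f"position {pos} outside chromosome {chrom!r}")

    def founders_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Vectorized founder lookup at sorted or unsorted positions."""
        segs = self.segments[chrom]
        bounds = np.fromiter((s[0] for s in segs), dtype=float, count=len(segs))
        labels = np.fromiter((s[2] for s in segs), dtype=np.int64, count=len(segs))
        idx = np.searchsorted(bounds, np.asarray(positions, dtype=float),
                              side="right") - 1
        return labels[idx]


def _merge_segments(segs):
    out = []
    for start, end, label in segs:
        if out and out[-1][2] == label:
            out[-1] = (out[-1][0], end, label)
        else:
            out.append((start, end, label))
    return [tuple(s) for s in out]


def merge_invisible_junctions(h: Haplotype) -> Haplotype:
    """Fuse adjacent same-founder segments. Idempotent (and already
    applied on construction; exposed for explicit use on raw mosaics)."""
    return Haplotype(h.genome, {c: list(s) for c, s in h.segments.items()})


@dataclass(frozen=True)
class Individual:
    """A diploid plant: two haplotypes plus provenance."""

    maternal: Haplotype
    paternal: Haplotype
    generation: str = ""
    scheme: str = ""

    def __post_init__(self) -> None:
        if self.maternal.genome is not self.paternal.genome and \
                self.maternal.genome != self.paternal.genome:
            raise ValueError("haplotypes defined on different genomes")

    @property
    def genome(self) -> Genome:
        return self.maternal.genome

    @property
    def is_homozygous(self) -> bool:
        return self.maternal.segments == self.paternal.segments

    @classmethod
    def founder(cls, genome: Genome, label: int, scheme: str = "") -> "Individual":
        h = Haplotype.pure(genome, label)
        return cls(h, h, generation="P", scheme=scheme)


def form_gamete(parent: Individual, params: MeiosisParams,
                rng: np.random.Generator) -> Haplotype:
    """One meiosis: sample counts and positions, random-walk the strands.

    Per chromosome the sampled count is the gamete's crossover budget:
    the transmitted chromatid starts on a fair-coin haplotype and
    switches at every crossover position. Same-founder junctions vanish
    in the merge step.
    """
    segments: dict[str, list[tuple[float, float, int]]] = {}
    for chrom, length in parent.genome.chromosomes:
        k = sample_crossover_count(params.count_dist, rng)
        pos = sample_crossover_positions(
            chrom, params.rec_map, k, params.min_separation, rng,
            params.max_resample,
        )
        current = int(rng.integers(2))
        haps = (parent.maternal.segments[chrom], parent.paternal.segments[chrom])
        bounds = np.concatenate([[0.0], pos, [float(length)]])
        segs: list[tuple[float, float, int]] = []
        for a, b in zip(bounds[:-1], bounds[1:]):
            if b > a:
                segs.extend(_slice_segments(haps[current], a, b))
            current ^= 1
        segments[chrom] = segs
    return Haplotype(parent.genome, segments)


def _slice_segments(segs, a: float, b: float):
    """Segments of one haplotype chromosome restricted to [a, b)."""
    out = []
    for start, end, label in segs:
        if end <= a:
            continue
        if start >= b:
            break
        out.append((max(start, a), min(end, b), label))
    return out
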
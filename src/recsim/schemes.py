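"""Population-construction programs built from single meioses.

Three scheme families are modelled:

* ``DH_SERIES`` — biparental cross, ``t - 1`` generations of single-seed
  selfing to reach the F_t plant, then doubled-haploid induction of one
  gamete of that plant ("F_t-DH").
* ``RIL`` — biparental cross followed by repeated single-seed-descent
  selfing (six generations by default); each near-homozygous line is
  read out as one mosaic.
* ``MAGIC`` — 2^k founders combined through a funnel of k intercross
  generations (8 parents: 4 F1s -> 2 F2s -> 1 F3), finished either by
  DH induction at the funnel's end (``DH``) or by five generations of
  single-seed selfing (``CS``). Post-DH selfing multiplies seed but adds
  no recombination, so it is not simulated.

Every line is simulated independently from its own deterministic RNG
stream spawned from the master seed, so populations are bit-reproducible
from (scheme spec, seed) and independent of evaluation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .genome import Genome
from .meiosis import Haplotype, Individual, MeiosisParams, form_gamete

__all__ = [
    "Scheme",
    "MagicMethod",
    "SchemeSpec",
    "Population",
    "cross",
    "self_cross",
    "dh_induce",
    "consensus_mosaic",
    "run_dh_series",
    "run_ril",
    "run_magic",
    "run_scheme",
]


class Scheme(str, Enum):
    DH_SERIES = "DH_SERIES"
    RIL = "RIL"
    MAGIC = "MAGIC"


class MagicMethod(str, Enum):
    DH = "DH"
    CS = "CS"


# funnel intercross depth per parent count: the generation whose plant
# is DH-induced (F3/F4/F5 for 8/16/32 parents)
_FUNNEL_DEPTH = {8: 3, 16: 4, 32: 5}
_MAGIC_SELFINGS_CS = 5


@dataclass(frozen=True)
class SchemeSpec:
    """Declarative description of one simulated population."""

    scheme: Scheme = Scheme.DH_SERIES
    dh_generation: int = 1          # DH_SERIES: t of the induced F_t plant
    selfing_generations: int = 6    # RIL
    n_parents: int = 2
    magic_method: MagicMethod = MagicMethod.DH
    n_lines: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "scheme", Scheme(self.scheme))
        object.__setattr__(self, "magic_method", MagicMethod(self.magic_method))
        if self.n_lines <= 0:
            raise ValueError("n_lines must be positive")
        if self.scheme is Scheme.MAGIC:
            if self.n_parents not in _FUNNEL_DEPTH:
                raise ValueError(
                    f"MAGIC requires n_parents in {sorted(_FUNNEL_DEPTH)}, "
                    f"got {self.n_parents}"
                )
        elif self.n_parents != 2:
            raise ValueError(f"{self.scheme.value} requires n_parents = 2")
        if self.scheme is Scheme.DH_SERIES and self.dh_generation < 1:
            raise ValueError("dh_generation must be >= 1")
        if self.scheme is Scheme.RIL and self.selfing_generations < 0:
            raise ValueError("selfing_generations must be >= 0")

    @property
    def label(self) -> str:
        if self.scheme is Scheme.DH_SERIES:
            return f"F{self.dh_generation}-DH"
        if self.scheme is Scheme.RIL:
            return f"RIL-F{self.selfing_generations + 1}"
        return f"{self.n_parents}p-{self.magic_method.value}-MAGIC"


@dataclass(frozen=True)
class Population:
    """A set of simulated lines plus the spec that produced them."""

    lines: tuple[Individual, ...]
    spec: SchemeSpec
    genome: Genome

    def __post_init__(self) -> None:
        if len(self.lines) != self.spec.n_lines:
            raise ValueError("line count does not match spec.n_lines")

    def __len__(self) -> int:
        return len(self.lines)

    def mosaics(self) -> list[Haplotype]:
        """One consensus mosaic per line (identity for homozygous lines)."""
        return [consensus_mosaic(ind) for ind in self.lines]


def cross(p1: Individual, p2: Individual, params: MeiosisParams,
          rng: np.random.Generator, generation: str = "", scheme: str = "") -> Individual:
    """Sexual cross: one gamete from each parent."""
    if p1.genome != p2.genome:
        raise ValueError("parents defined on different genomes")
    return Individual(form_gamete(p1, params, rng), form_gamete(p2, params, rng),
                      generation=generation, scheme=scheme)


def self_cross(p: Individual, params: MeiosisParams,
               rng: np.random.Generator, generation: str = "") -> Individual:
    """Self-pollination: two independent gametes from the same plant.

    Under single seed descent exactly one such offspring is retained per
    line per generation — which is exactly one call to this function.
    """
    return Individual(form_gamete(p, params, rng), form_gamete(p, params, rng),
                      generation=generation, scheme=p.scheme)


def dh_induce(p: Individual, params: MeiosisParams,
              rng: np.random.Generator, generation: str = "") -> Individual:
    """Doubled-haploid induction: one gamete duplicated into both haplotypes."""
    g = form_gamete(p, params, rng)
    return Individual(g, g, generation=generation, scheme=p.scheme)


def consensus_mosaic(ind: Individual) -> Haplotype:
    """One founder mosaic per line.

    Homozygous (DH) lines return their haplotype. Near-homozygous RIL
    lines carry residual heterozygous segments (~2^-t of the genome
    after t selfings); these are resolved deterministically by reporting
    haplotype 1's founder label, so the consensus is haplotype 1.
    """
    return ind.maternal


def _line_rngs(seed: int, n_lines: int) -> list[np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(n_lines)
    return [np.random.default_rng(s) for s in children]


def _make_f1(genome: Genome, scheme: str) -> Individual:
    """Biparental F1: pure founder-0 / pure founder-1 (no randomness)."""
    return Individual(Haplotype.pure(genome, 0), Haplotype.pure(genome, 1),
                      generation="F1", scheme=scheme)


def run_dh_series(spec: SchemeSpec, params: MeiosisParams) -> Population:
    """F_t-DH population: t−1 selfings from the F1, then DH induction."""
    t = spec.dh_generation
    genome = params.genome
    lines = []
    for rng in _line_rngs(spec.seed, spec.n_lines):
        plant = _make_f1(genome, spec.label)
        for g in range(2, t + 1):
            plant = self_cross(plant, params, rng, generation=f"F{g}")
        lines.append(dh_induce(plant, params, rng, generation=f"F{t}-DH"))
    return Population(tuple(lines), spec, genome)


def run_ril(spec: SchemeSpec, params: MeiosisParams) -> Population:
    """RIL population by single seed descent from an F1."""
    genome = params.genome
    lines = []
    for rng in _line_rngs(spec.seed, spec.n_lines):
        plant = _make_f1(genome, spec.label)
        for g in range(spec.selfing_generations):
            plant = self_cross(plant, params, rng, generation=f"F{g + 2}")
        lines.append(plant)
    return Population(tuple(lines), spec, genome)


def run_magic(spec: SchemeSpec, params: MeiosisParams) -> Population:
    """MAGIC population: per-line funnel, finished by DH or selfing.

    Each line runs its own funnel over a fresh random permutation of the
    founders, so funnels are independent and founder order is balanced
    only in expectation.
    """
    depth = _FUNNEL_DEPTH[spec.n_parents]
    genome = params.genome
    lines = []
    for rng in _line_rngs(spec.seed, spec.n_lines):
        order = rng.permutation(spec.n_parents)
        layer = [Individual.founder(genome, int(f), scheme=spec.label)
                 for f in order]
        gen = 0
        while len(layer) > 1:
            gen += 1
            layer = [
                cross(layer[i], layer[i + 1], params, rng,
                      generation=f"F{gen}", scheme=spec.label)
                for i in range(0, len(layer), 2)
            ]
        plant = layer[0]  # the F_depth funnel hybrid
        if spec.magic_method is MagicMethod.DH:
            # post-DH selfing only multiplies seed; no new recombination
            plant = dh_induce(plant, params, rng, generation=f"F{depth}-DH")
        else:
            for s in range(_MAGIC_SELFINGS_CS):
                plant = self_cross(plant, params, rng,
                                   generation=f"F{depth + s + 1}")
        lines.append(plant)
    return Population(tuple(lines), spec, genome)


def run_scheme(spec: SchemeSpec, params: MeiosisParams) -> Population:
    """Dispatch on ``spec.scheme``."""
    if spec.scheme is Scheme.DH_SERIES:
        return run_dh_series(spec, params)
    if spec.scheme is Scheme.RIL:
        return run_ril(spec, params)
    return run_magic(spec, params)
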
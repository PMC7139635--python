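"""recsim: forward simulation of meiotic recombination patterns in
doubled-haploid, RIL and MAGIC breeding populations.

The engine draws per-chromosome crossover counts from an empirical
distribution and crossover positions from a window-level recombination
landscape, composes meioses into breeding schemes, and summarizes the
resulting founder mosaics (events per line, fragment lengths,
recombination bins) including Kosambi linkage-map construction.
"""

from .genome import (
    Genome,
    WindowGrid,
    build_genome,
    default_maize_genome,
    make_window_grid,
    read_genome,
    write_genome,
)
from .ratemap import (
    RecombinationMap,
    SyntheticMapParams,
    generate_synthetic_map,
    normalize_map,
    read_map,
    write_map,
)
from .meiosis import (
    RAW_COUNT_PROBS,
    CrossoverCountDistribution,
    Haplotype,
    Individual,
    InterferenceFallbackWarning,
    MeiosisParams,
    form_gamete,
    merge_invisible_junctions,
    renormalize_count_dist,
    sample_crossover_count,
    sample_crossover_positions,
)
from .schemes import (
    MagicMethod,
    Population,
    Scheme,
    SchemeSpec,
    consensus_mosaic,
    cross,
    dh_induce,
    run_dh_series,
    run_magic,
    run_ril,
    run_scheme,
    self_cross,
)
from .popstats import (
    BinMap,
    SummaryStats,
    build_bin_map,
    count_breakpoints,
    per_line_fragment_length,
    pooled_fragment_stats,
    summarize,
)
from .linkage import (
    GenotypeMatrix,
    LinkageMap,
    adjacent_recfrac,
    build_linkage_map,
    genotype_matrix,
    kosambi,
    map_correlation,
    ril_correction,
)

__version__ = "0.1.0"


def default_params(
    window_size: int = 125_000,
    map_seed: int = 0,
    genome: Genome | None = None,
    rec_map: RecombinationMap | None = None,
) -> MeiosisParams:
    """Meiosis parameters under the bundled study conditions.

    Default maize genome, synthetic 125 kb landscape calibrated to a
    3.48 cM mean and 12.1 cM cap, the renormalized empirical crossover
    count distribution, and the 10 Mb interference rule.
    """
    if rec_map is None:
        genome = genome or default_maize_genome()
        grid = make_window_grid(genome, window_size)
        rec_map = generate_synthetic_map(grid, SyntheticMapParams(), seed=map_seed)
    return MeiosisParams(
        count_dist=CrossoverCountDistribution.from_raw(),
        rec_map=rec_map,
    )


def simulate(spec: SchemeSpec, params: MeiosisParams | None = None) -> Population:
    """Run one breeding scheme under ``params`` (defaults bundled)."""
    return run_scheme(spec, params or default_params())
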
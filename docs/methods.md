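# Methods

## Model

`recsim` simulates breeding-population construction as a sequence of
meioses over founder-labelled chromosome mosaics ("gene dropping"). No
sequence is tracked: a haplotype is, per chromosome, an ordered list of
`(start, end, founder)` segments covering `[0, length)` in bp, with
adjacent same-founder segments always merged so that every stored
junction is an observable recombination breakpoint.

One meiosis, per chromosome:

1. Draw a crossover count k from the empirical count distribution.
2. Draw k positions: each picks a window with probability
   `p_w = c_w / Σ_chrom c_w` and a uniform offset within it. The whole
   k-set is redrawn until all pairwise distances are ≥ 10 Mb; k itself
   is never altered.
3. Transmit a single chromatid by a random walk: a fair coin chooses
   the starting parental haplotype and every crossover position switches
   strands. The sampled count is therefore the gamete's junction budget,
   matching how the counts were measured (breakpoints per chromosome per
   DH line).

Assumptions deliberately made (and their consequences):

* **One count distribution for all chromosomes.** The empirical counts
  are genome-aggregated; a length-proportional mode is not enabled by
  default. Long and short chromosomes receive the same crossover-count
  law, so per-chromosome (as opposed to per-genome) statistics are only
  approximate.
* **No obligate chiasma, no gene conversion, no four-strand chiasma
  bookkeeping.** Interference is only the hard 10 Mb minimum-distance
  rule.
* **Crossovers in homozygous regions are silent.** They are simulated
  and then vanish in the merge step — this is what makes the DH-series
  mean saturate instead of growing linearly in the selfing generation.

### Count distribution

The empirical per-chromosome rates for 0/1/2/3 crossovers are
0.16/0.30/0.23/0.15. They sum to 0.84; we renormalize over the support
{0..3}, giving p = (0.1905, 0.3571, 0.2738, 0.1786) and a mean of
1.4405 crossovers per chromosome (≈ 14.4 per ten-chromosome meiosis).
Renormalization — rather than assigning the missing 0.16 mass to counts
≥ 4 — is the only reading consistent with the observed F1-DH mean of
~14 events per line; pushing the residual mass to 4+ forces a mean ≥ 18.

### Expected behaviour (closed-form oracles used in tests)

With m = 14.405 expected junctions per gamete from a fully heterozygous
plant, junction bookkeeping gives the classical map-expansion results:

* DH induced at selfing generation t of a biparental:
  `m · (2 − 2^(1−t))` — 14.4, 21.6, 25.2, … → 28.8.
* Selfing-RIL observed fraction R relates to the single-meiosis
  fraction as `R = 2r/(1+2r)` (Haldane–Waddington), inverted before the
  Kosambi transform as `r = R/(2−2R)`.
* MAGIC funnels add one full meiosis layer of junctions per intercross
  generation: `m·k` after k layers, e.g. 43.2 for an 8-parent funnel
  DH-induced at F3.

The simulations are validated against these oracles (3-SE bands), a
junction-survival probability of 1/2 under crossover-free transmission,
the `0.5^t` selfing heterozygosity recursion, and a chi-square
goodness-of-fit of crossover placement against the window probabilities.

## Synthetic recombination landscape

The real window-level landscape is an empirical table we do not ship;
the generator produces a synthetic stand-in with its stated gross
properties. Per window, a gamma(shape = 0.7) draw gives strong right
skew (most recombination in a minority of windows, hotspot-like); a
random 10% of windows is zeroed (recombination deserts); windows within
the central 20% of the chromosome are multiplied by 0.1 (centromere
suppression, centromere at mid-chromosome by default — real maize
centromeres are not all central, but only the relative landscape
matters). Rates are then scaled by the factor s solving
`mean(min(s·r, max_rate)) = target_mean` (monotone in s, solved with
Brent's method to 1e-12), so the genome-wide mean is exactly 3.48 cM per
125 kb window and no window exceeds 12.1 cM.

The absolute cM scale of the weights is treated as relative only: the
published per-window means summed genome-wide exceed any plausible total
map length, and the scale cancels in the placement normalization
`p_w = c_w / Σ c_w`, so nothing downstream depends on it.

What the synthetic landscape does **not** reproduce: the real map's
autocorrelation structure (neighbouring windows are drawn
independently), the true centromere positions, and the exact weight
distribution. Statistics that depend only on counts and coarse placement
(events per line, map self-consistency) transfer to real data; bin
counts and pooled fragment-length quantiles depend on the real weight
distribution and are reported as qualitative trends only (e.g. the
pooled median decreases from F1-DH to F6-DH, which the tests assert).

## Breeding schemes

* **DH series** (`dh_generation = t`): biparental F1, then t−1
  single-seed-descent selfings, then one gamete doubled. t counts the
  generation of the induced plant (t = 1 induces the F1). All outputs
  are exactly homozygous.
* **RIL**: F1 plus six SSD selfings by default. Residual heterozygous
  segments (expected 2⁻⁶ ≈ 1.6% of genome) are resolved by reading
  haplotype 1's label — deterministic, and equivalent in expectation to
  any other single-mosaic readout.
* **MAGIC**: per line, an independent funnel over a fresh random
  permutation of the 2^k founders (8 parents: 4 F1 → 2 F2 → 1 F3),
  finished either by DH induction of the funnel hybrid (8/16/32 parents
  induce at F3/F4/F5) or by five SSD selfings ("CS"). Post-DH selfing
  generations only multiply seed and add no recombination, so they are
  not simulated.

## Statistics

* **Events per line**: observable founder switches summed over
  chromosomes of the line's mosaic.
* **Per-line fragment length**: total physical genome length / events,
  in Mb; undefined (NaN) at zero events. This is the per-line readout
  and lives on the hundreds-of-Mb scale by construction.
* **Bin map**: every line's breakpoints snapped to the start of their
  125 kb window (configurable), pooled and deduplicated per chromosome;
  bins are the segments between consecutive distinct positions and the
  chromosome ends. Pooled fragment statistics (mean/median/sd, sub-Mb
  scale) are computed over bin lengths. Both fragment readouts are
  reported, clearly labelled, because they answer different questions
  (per-line granularity vs population mapping resolution).
* **Linkage maps**: markers at window midpoints, order fixed to
  physical order (maps are anchored to the reference assembly; no
  de-novo grouping/ordering). r per adjacent interval is the fraction of
  lines whose codes differ; DH uses r directly, RIL corrects first.
  Kosambi input is clipped to [0, 0.4999] with a warning (the transform
  diverges at 0.5). Map comparisons evaluate cumulative cM at the
  coarser map's marker positions, taking in the finer map the last
  marker at or before each point (interpolation-free), pooled over
  chromosomes.

## Defaults and units

| parameter | default | unit | why |
|---|---|---|---|
| genome | 10 chromosomes, 2,056 Mb | bp | bundled B73-like rounded lengths; config-overridable |
| window size | 125,000 | bp | the resolution at which the empirical rates are most accurate |
| target mean rate | 3.48 | cM/window | empirical 125 kb mean |
| max rate | 12.1 | cM/window | empirical 125 kb maximum |
| zero fraction | 0.10 | — | unconstrained by the source data; plausible desert share |
| centromere span / factor | 0.20 / 0.10 | — | produces the observed larger centromeric fragments |
| min crossover separation | 10,000,000 | bp | hard interference rule |
| count probabilities | 0.16/0.30/0.23/0.15 renormalized | — | empirical DH counts |
| population size | 200 | lines | the studied population size |
| RIL selfings / CS-MAGIC selfings | 6 / 5 | generations | standard SSD schedule; CS endpoints F8/F9/F10 |

All coordinates are 0-based half-open bp, including files. Text outputs
format floats to 6 decimals so identical (config, seed) runs are
byte-identical.

## Randomness and reproducibility

A master seed spawns one child `SeedSequence` per line; each line is
simulated from its own stream with a fixed in-line draw order, so
populations are bit-reproducible from (spec, seed) and independent of
evaluation order. A consequence of common random numbers worth knowing:
under the same seed, scheme variants that share their initial draw
sequence (e.g. an F6-DH line and the haplotype-1 readout of a
six-selfing RIL) can coincide exactly; use distinct seeds to compare
schemes independently.

## Numerical / degenerate-input choices

* Rejection sampling of crossover positions caps at 1,000 attempts;
  geometrically impossible separations (e.g. 3 crossovers ≥ 10 Mb apart
  on a 25 Mb chromosome) fall back to the best-spread sample seen and
  emit an `InterferenceFallbackWarning` rather than looping forever.
* A chromosome whose rates are all zero cannot place crossovers; map
  normalization raises an error naming it.
* Zero-breakpoint lines yield NaN per-line fragment length; populations
  with no breakpoints at all yield one bin per chromosome and degenerate
  (well-defined) pooled statistics.
* Observed RIL fractions ≥ 0.5 are clipped before the selfing
  correction, with a warning.

## Problem sizes

The bundled analyses use 200-line populations on the full ~2 Gb genome
with 16,448 windows at 125 kb; a full acceptance run (all schemes, three
seeds each) completes in about a minute on one CPU. The test suite uses
smaller line counts (40–150) for engine-validation properties where the
3-SE criterion already has power, and the full 200 lines for the
headline population means.

## Known limitations

Gene conversion, obligate chiasma, chromosome-length-dependent crossover
counts, environmental and paternal effects, and selection are all
unmodelled. Real RIL populations show more events (~34) than the selfing
model predicts (~28), consistent with processes outside this model
(e.g. small fragments from additional rounds of intermating or gene
conversion). Bin counts from the synthetic landscape should not be
compared numerically against bin counts derived from the real map.
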
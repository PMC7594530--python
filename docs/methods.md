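# Methods

## The model frame

All objects live on a `FusionArchitecture`: `U` ancestral haploid
chromosome units plus `F` pairwise-disjoint candidate fusion sites, each an
unordered pair of unit indices. A fusion and a fission are the same site
seen from opposite directions, so one biallelic state (fused/unfused) per
site suffices. A race fixes a subset of sites fused; a diploid genotype
carries an unordered allele pair per site; a gamete one allele per site.
Translocations, inversions, within-chromosome recombination and any
sequence content are outside the model.

The default frame has `U = 53` and `F = 25` sites pairing units
(1,2)…(49,50), with two presets: `spanish` (no fusions, haploid 53,
2n = 106) and `swedish` (sites 1–24 fused, haploid 29, 2n = 58; site 25 is
left polymorphic, so a 24/25-fused heterozygote reproduces the observed
n = 28, m = 57 karyotype). This frame reproduces every parental and F1
figure in the published count table exactly. "At least 24" differences is
all the data pin down; `F` is a free parameter throughout.

Meiotic-figure prediction is deterministic: per heterozygous site one
trivalent; per fused/fused site one bivalent; per unfused/unfused site two
bivalents; per invariant unit one bivalent. Univalents (`s`) are treated
purely as observation noise — imperfect pairing — and are never predicted,
matching the convention that they are excluded from both `n` and `m`.

## Count decomposition and generation summaries

`decompose(n, m)` solves `y = m − 2n`, `x = n − y`, feasible exactly when
`2n ≤ m ≤ 3n`; infeasible input raises an error naming the violated bound.
Numerical conventions chosen to match the published table digit-for-digit:

- multiple MI counts per specimen are reduced to the modal value (ignoring
  univalent annotations), ties broken toward the smaller count;
- a ranged diploid count (`ca106–108`) contributes its low endpoint and
  marks the result approximate;
- the homozygosity proportion `100·2x/m` is rounded half-up to 1 decimal;
  generation means to 1 decimal and sample SDs (n−1 denominator) to 2,
  computed on unrounded proportions.

Published-table caveats, surfaced but not "fixed": row 12Z051 prints
(x=5, y=25) for (n=29, m=82), violating `2x+3y=m` (decomposition gives
(5, 24)); loading the fixture emits a warning and keeps the printed values
as provenance. The published F1 mean (11.2 ± 2.14) is reproducible only
from a 5-record subset that excludes 12Z051; our F1 summary uses all six
eligible records (11.4 ± 1.95). The published F4 range low end (43.0%)
excludes one specimen (41.5%) that its own mean includes; we report the
computed range.

The generation-effect test is a classical one-way ANOVA F whose p-value
comes from ≥10,000 random label permutations (`(1 + #{F* ≥ F})/(1 + B)`),
avoiding normality assumptions on 6–10 specimens per group. Pairwise
contrasts use the Tukey–Kramer statistic
`q = |m_i − m_j| / sqrt(MSW/2·(1/n_i + 1/n_j))` against the same
permutation null, Holm-adjusted. This is a permutation analogue of the
unequal-N HSD family of tests: it reproduces the qualitative structure
(only F1 differs, p < 0.001) without studentized-range table lookups. The
permutation p is resolution-limited at `1/(B+1)`.

## Segregational model

With `h` heterozygous sites and independent 50:50 segregation per
trivalent, the balanced-gamete pool has `2^h` types at frequency `1/2^h`.
`enumerate_balanced_gametes` materializes the list only up to a limit
(default `2^16` types) and stays analytic above it, so the 24-site case
(`2^24` types) costs nothing. `punnett_square` forms all ordered gamete
pairs, merges zygotes that are identical as unordered per-site allele
pairs into classes with summed probabilities, and classifies each
homozygous class against the two parental karyotypes; `cell_count` still
reports the full ordered square. Probabilities are exact `Fraction`s end
to end (they sum to exactly 1; `r(24)` prints 0.99999988 at 8 decimals),
converted to float only in reports.

`r = 1 − 2/2^h` counts homozygous *classes*, not probability mass; the
class probabilities are available on the result for anyone wanting the
mass-weighted variant. Parental karyotypes default to the all-unfused
(P1) and all-fused (P2) homozygotes over the variable sites — exact for
any F1 of two homozygous races — and can be passed explicitly otherwise.
Unbalanced meiotic products are not enumerated; their cost appears only as
the fitness discount in the simulator.

## Wright–Fisher sorting simulator

Discrete non-overlapping generations (the 4N and `(1 − 1/2N)^t` arguments
are Wright–Fisher diffusion statements); monoecious individuals;
self-pairing excluded. Each offspring draws two distinct parents with
probability proportional to fecundity weight, then one balanced gamete per
parent (per heterozygous site an independent fair coin). Census sizes are
a per-generation list, recycled over the horizon — the default experiment
sizes (8, 12, 24, 40) give harmonic-mean N ≈ 14.55 ≈ 15. The founder
population is 100% F1 heterozygotes (the laboratory cross); a
(P1, P2, F1) mixture founder is available for hybrid-zone-like starts.

Fitness modes: `neutral` (default — the chromosomal model's baseline);
`flat_hybrid`, weight `w` (default 0.42, the observed aggregate hybrid
fitness) for any individual with ≥1 heterozygous site; `per_site`,
`w_site^h` with `w_site = 0.42^(1/24)` so a fully heterozygous F1 lands on
0.42. The data do not distinguish whether the 42% is fecundity, viability
or both compounded; it is implemented as a single per-generation fecundity
weight, and the flat/per-site split is offered because both decompositions
are defensible. Under `monogamous_pairs` mating the population is shuffled
into fixed pairs and offspring assigned to pairs equiprobably; fitness
weights act only under random mating.

Reproducibility: one root seed; replicate `r` uses a numpy
`SeedSequence((seed, r))` stream, so results are bit-reproducible and
replicates independent. A replicate stops evolving once every site is
fixed population-wide (the state is then absorbing) and its trajectory is
padded constant.

Reports deliberately print both fixation horizons: the classical upper
bound 4N and the diffusion mean from frequency ½, `4N ln 2 ≈ 2.77N`.

## Synthetic observation tables

The generator emulates the texture of real count tables: per-specimen MI
cells whose element count is the true `n`, univalent annotations drawn per
trivalent per cell (`Binomial(y, p_univalent)`) that populate `s` without
touching `n` or `m` — modelling pairing failure as n-altering would
contradict the decomposition formulas the field actually uses — plus
`ca` flags (`p_ca`) and missing diploid counts (`p_missing_m`). The
published table gives no univalent rate; the default `p_univalent = 0.1`
is a placeholder, not a measured value, and `p_ca = 0.8` / `p_missing_m =
0.1` reflect the rough frequency of `ca` flags and missing cells in the
published hybrid rows. Noiseless generation followed by the full parse →
decompose → summarize pipeline recovers the generating truth exactly; that
round trip validates the pipeline's bookkeeping, not the biology of real
preparations (overlapping chromosomes, true miscounts and reciprocal
errors in `n` and `m` are not modelled).

## Problem sizes used in the test suite

Chosen as the smallest sizes at which each check is statistically sharp:
exact Markov-chain comparison of N=2 single-site absorption times with
5,000 replicates (KS at α = 0.01 against a brute-force 6-state chain);
heterozygosity decay at N=25 over 20 generations × 800 replicates against
`½(1 − 1/2N)^t` within 0.03 absolute (the no-selfing correction and the
non-equilibrium founder contribute ~2% systematic deviation, below that
band); the 3-site novel-karyotype fraction over 400 replicates against
0.75 within 3 binomial SE; the 24-site, N=15 run over 200 replicates for
the median-fixed-by-4N check; 200 hypothesis cases for the noiseless
round trip; 100 simulated experiments for the F1→F4 sign test; full
Punnett enumeration up to h = 10 (1,048,576 ordered cells).

## Known limitations

Sites segregate independently (no linkage between fusion sites, no meiotic
drive); no mutation introducing new fusions; no spatial structure or gene
flow from parental races; two-sex demography is not modelled (the drift
arithmetic uses census N). The permutation pairwise procedure is an
analogue, not a reimplementation, of tabulated unequal-N HSD critical
values. `r` compares karyotype classes, so it speaks to the *variety* of
outcomes; the probability that a given population fixes a novel karyotype
is the simulator's job, and matches `r` only under neutrality with
independent sites.
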
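# Methods

## The half-sib design and what is being estimated

In a paternal half-sib family a single sire is mated to many dams and each
progeny receives one recombined paternal gamete.  At a marker where the
sire is heterozygous (dosage 1) a homozygous progeny reveals the
transmitted paternal allele: dosage 0 implies paternal allele 0, dosage 2
implies allele 1.  A heterozygous or missing progeny genotype reveals
nothing, and sire-homozygous markers are never informative.  Everything in
the package builds on this observation: recombination is *counted*, not
modelled, and the only modelling happens afterwards, when genetic-map
functions are fitted to the counted rates.

Only paternal recombination is estimated — dams are unobserved and
maternal crossovers are invisible to the design.

## Sire phasing and origin labelling

The transmitted alleles of many progeny are chained into sire haplotypes
by a greedy majority rule over consecutive sire-heterozygous markers: for
each adjacent pair, the progeny informative at both either mostly
transmit equal alleles (markers linked "in phase") or mostly opposite
ones ("in repulsion").  Ties count as in-phase so output is
deterministic.  When no progeny is informative at both markers of a pair
the link is unresolved and the chromosome splits into *phase blocks*;
origin labels are only comparable within a block and no rate is pooled
across blocks.  The two haplotypes are recovered up to a global flip per
block; every downstream statistic is invariant under that flip (this
gauge invariance is tested).

This is a deliberately transparent re-derivation of the deterministic
half-sib phasing idea; block-construction heuristics of more elaborate
phasing software are not reproduced.

## Recombination rates

For each pair of markers, θ̂ is the pooled fraction of recombinant
meioses: counts (not per-family rates) are summed over families, which
weights every informative meiosis equally and matches the binomial
sampling model.

*Adjacent rates.* The per-interval estimate pools only families whose
consecutive-heterozygous pair spans exactly that interval, which keeps the
estimator unbiased for the interval's own θ.  A family whose informative
gap spans several intervals contributes to the per-interval table only
when the entire span is non-informative in *every* family (e.g. a marker
at which all sires are homozygous); the pooled gap estimate is then
attributed to the gap's last interval, so the cumulative map conserves
total length across the gap.  Gap counts that overlap partially informative
intervals are discarded rather than smeared over them — attributing a
multi-interval gap's recombination probability (≈ the *sum* of the spanned
θs) to a single interval would inflate that interval's rate by roughly the
reciprocal of the sire heterozygosity.

*Pairwise rates.* All p(p−1)/2 intra-chromosomal pairs are counted per
family with simple indicator-matrix products and pooled; entries with no
informative meioses are omitted.  Rows are emitted in the column-major
order of the upper triangle, which is the ordering the scatter-thinning
step assumes.  θ̂ > 0.5 is retained, not clipped — such values flag
phasing errors or misplaced markers and should stay visible.

## Genetic maps

*Cumulative map*: d₁ = 0 and d_{k+1} = d_k + θ̂_k, in Morgan.  Monotone by
construction; genetic length equals the sum of informative interval rates
exactly.

*Smoothed map*: positions minimise Σ w_ij (θ̂_ij − (d_j − d_i))² over all
pairs with θ̂ strictly below the admission cutoff (default 0.05), subject
to d monotone and d₁ = 0.  Small recombination fractions are nearly
additive in map distance, which justifies the linear model.  In terms of
the non-negative increments g_k = d_{k+1} − d_k this is a sparse
non-negative least-squares problem, solved deterministically with
`scipy.optimize.lsq_linear`; weights are informative-meiosis counts
(an unweighted option exists).  Markers appearing in no admitted pair are
placed by linear interpolation in bp between their nearest constrained
neighbours and flagged.

**Known limitation — selection at the cutoff.**  Admitting pairs by their
*estimated* rate truncates the sampling noise of pairs whose true rate is
near the cutoff: only downward fluctuations are admitted, which biases the
smoothed map short when per-pair informative counts are small.  The effect
shrinks as the per-pair standard error √(θ(1−θ)/n_inf) becomes small
relative to the cutoff; at the pedigree scales the method is meant for
(hundreds of thousands of meioses) it is negligible, but on desk-scale
simulations the smoothed map can be visibly shorter than the cumulative
map.  Tests of smoothed/cumulative agreement therefore use low-θ
simulations where all admitted pairs sit far from the cutoff.

## Genetic-map functions

Four single-parameter families relate map distance d (Morgan) to
recombination fraction; their closed forms, domains and special cases are
documented in `linkmap.mapfun`.  Rao's system is defined through its
distance function d(θ | a); the forward value is obtained by Brent root
finding on θ ∈ [0, ½) with absolute tolerance 1e−10, which is exercised by
round-trip and special-case identity tests (Morgan, Carter–Falconer,
Kosambi, Haldane).  Distances beyond a family's representable range
saturate at θ = ½.

Fitting minimises the unweighted sum of squared deviations over the
supplied (d_ij, θ̂_ij) pairs: bounded scalar (Brent) minimisation with
xatol = 1e−10 for the continuous families — the exact domain endpoints are
also evaluated, since a boundary optimum is otherwise unreachable — and
exhaustive search over N ∈ {2, 3, 4, 5} for the binomial family.
Non-finite pairs are skipped and counted.  The family with the smallest
SSE is selected; exact ties fall back to a fixed family order and are
logged.  Fits carry a hash of their pair set so that selection across
families computed on different data is rejected.

Distances can come from either map; the smoothed map is the default in
the Results facade because it uses all pairwise information.  Both maps
measure distance in recombination-fraction-sum units, so a unit Haldane
scale is only expected when fitting against true (model) distances.

## Simulator

The generator emulates the study conditions the estimators are meant for:
each sire's two haplotypes are drawn from per-marker population allele
frequencies, each progeny's paternal gamete follows a two-state Markov
chain along the chromosome with switch probability θ_k per interval (no
crossover interference — the Haldane model), and the maternal allele is an
independent population draw.  Defaults, chosen once as a desk-scale
version of a dense cattle half-sib pedigree: 200 families × 50 progeny,
100 markers evenly spaced on a 100-Mbp chromosome, adjacent θ ~
U(0.002, 0.02) (≈ 1.1 M per 100 Mbp, the ~1 cM/Mbp cattle genome
average), allele frequencies U(0.3, 0.7) as after MAF filtering on an
array, genotyping-error rate 0 (QC tests enable it).

What the simulator does **not** emulate: crossover interference, maternal
recombination and linkage disequilibrium between dam haplotypes, assembly
errors (misplaced markers), array clustering artefacts, and family-size
imbalance.  Passing tests therefore demonstrate correctness of the
counting, phasing, placement and fitting machinery under the stated
sampling model — not robustness to assembly flaws or interference, which
real data exhibit.

## Quality control

Three genotype-level rules, applied in this order by the model facade:
optional marker blocklist (e.g. ids reported as misplaced), minor-allele
frequency filter (keep iff MAF strictly > 0.01 by default; MAF is computed
over all non-missing dosages of all individuals and folded so it is
coding-invariant), and the opposite-homozygote Mendelian check
(conflicting progeny genotypes set to missing, never removed markers).
Missing genotypes are not imputed; they simply render the meiosis
non-informative downstream.  All filters are idempotent.

## Hotspot detection

An interval is flagged when θ̂ exceeds mean + m·SD (strict), with mean and
SD taken over all non-missing adjacent rates of the *whole genome* — also
when a single chromosome is displayed — and m = 2.5 by default.  The SD
uses the sample (n−1) denominator, pinned by a test.  NA intervals never
enter the statistics and are never flagged.  Raising the multiplier can
only remove flags.

## Statistical testing conventions

Simulation-recovery tests compare estimates to truth in units of binomial
standard errors.  Where ~100 intervals are tested simultaneously, a
literal "all within 3 SE" assertion would fail a correct estimator with
appreciable probability (per-interval 3-SE coverage is 99.5–99.9%, and
small-count binomials have fat discrete tails), so those tests assert that
at least 97% of intervals fall within 3 SE and all within 6 SE — still
sensitive to any systematic bias — while pooled quantities (total map
length) use a single 3-SE band.  Optimiser-vs-grid checks use 10⁵-point
grids for the closed-form families and ~10³ points for Rao, whose forward
evaluation requires a root-find per point; the comparison asserts the
optimiser's SSE is no worse than the grid minimum.

## Problem sizes

Test and acceptance runs use the default 200 × 50 × 100 design
(10,000 meioses, 4,950 marker pairs), 20 replicates of a 100 × 100 × 60
hotspot design, and 1.2 million synthetic points for the thinning cap —
sizes at which every check completes in seconds to a few minutes on one
CPU while keeping binomial standard errors small enough to be
discriminating.
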
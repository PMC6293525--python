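# Methods

This note documents the models, estimators and numerical choices behind
`ccqg`, and what the bundled simulator does and does not emulate.

## Breeding simulator

A CC line is bred explicitly, meiosis by meiosis.  The funnel is the
canonical 8→4→2→1 scheme: four pairwise crosses of inbred founders (G1),
two four-way crosses (G2), one eight-way cross producing a sibling pair,
then `n_inbreeding_gens` generations of brother–sister mating (default 20,
matching the convention that CC lines are treated as inbred around F20;
the true generation of any real line varies and is not modelled).  Funnel
order is randomized per line unless supplied; `funnels="balanced"` uses
cyclic rotations of random permutations so each founder occupies each
funnel position equally often per block of eight lines.

Crossovers follow a Poisson process on the cM scale (Haldane model: one
crossover per 100 cM per meiosis, no interference).  This makes the
two-locus behaviour analytically checkable: for loci at recombination
fraction r, an eight-way sib-mated RIL approaches founder-switch
probability R = 7r/(1+6r), and the test suite verifies the simulator
against both an independent two-locus pedigree simulation and this limit.
Residual heterozygosity is *retained*, not forced away — finite inbreeding
leaves ~0.1–1% heterozygous genome at 20 generations, which downstream
stages must tolerate.  Genomes are autosomal only; X-linked inheritance,
line extinction and selection during inbreeding are out of scope.

Genotyping applies, per marker, a symmetric error (probability
`error_rate`, the call is replaced by a uniformly chosen different dosage)
and missingness (`missing_rate`, encoded `NA` in files, −1 in memory).
Synthetic physical coordinates are laid out at 2 Mb per cM, the mouse
genome-wide average.

Phenotypes are built additively per animal: intercept + QTL effects (the
mean of the two haplotypes' founder effects at each QTL position, read
from the true mosaic) + a line-level polygenic draw with covariance
σ²_g·K + age/batch/origin covariate effects + N(0, σ²_e) noise.  Age is
drawn uniformly in 56–112 days, batch per animal, origin per line (it is a
property of where a line was bred).  The generator records the true
h² = σ²_g/(σ²_g+σ²_e) in the table's metadata.  What the simulator does
*not* emulate: real MUGA/MegaMUGA marker content and ascertainment,
non-Gaussian trait distributions (e.g. zero-inflated grooming durations),
shared-cage effects, and dominance or epistasis — so passing tests
demonstrate correctness of the estimators under their own model, not
robustness to every feature of real behavioral data.

## Mosaic reconstruction

The HMM has eight hidden states, one per *homozygous* founder — a
deliberate reduction from the 36-diplotype state space, justified because
lines are near-inbred.  Heterozygous stretches and genotyping errors both
surface through the emission ε: a call emits 1−ε when it equals twice the
founder allele and ε/2 otherwise (missing emits 1 in every state).  A
heterozygous call is never expected under any state, so residual
heterozygosity appears as locally flat posteriors rather than wrong hard
calls; regions where founders share identical haplotypes likewise stay
flat — no arbitrary tie-breaking.  Default ε = 0.01.

Transitions over a gap of d cM use
r_eff = (1 − exp(−a·d/50))/2, capped at 7/8 to keep the chain proper on
sparse maps, split evenly over the seven other founders.  The
map-expansion factor a (default 2, between an F2 and the full RIL limit)
is exposed as a parameter because the effective expansion of any given
panel depends on its inbreeding history.  Posteriors come from the scaled
forward–backward recursion (per-step normalization; no underflow for
arbitrarily long chromosomes); the symmetric transition lets each step run
in O(8) per state update.  Viterbi runs in log space with a top-2 trick
for the exchangeable transition.  The suite checks the recursion exactly
against exhaustive path enumeration on short chromosomes, and checks
accuracy (≥95% correct founder labels at 0.5 cM spacing, ε = 0.01) against
simulation truth.

Probabilities attach to marker-midpoint intervals, 0-based half-open in bp,
with cM widths that tile each chromosome (used for cM-weighted founder
shares).  Pruning to ~N intervals walks each chromosome greedily, jumping
to the marker nearest one adaptive step ahead, always retaining
chromosome endpoints; rows remain normalized and genome-wide founder
contributions are preserved to <0.01.

## Heritability

Kinship is the unweighted interval average
K[i,j] = (1/M) Σ_m Σ_f p[i,m,f]·p[j,m,f] — the expected probability that
two lines descend from the same founder.  It is used as-is (no double
centering); a unit-mean-diagonal rescaling is available but not applied by
default, so σ²_g is on the scale of "fully shared genome" variance.

Narrow-sense h² is fitted at the *animal* level: animals of lines i, j
share covariance σ²_g·K[i,j], giving V = σ²_g·ZKZ' + σ²_e·I.  Writing
V = σ²_p(h·A + (1−h)·I) with A = ZKZ' and h = h², one eigendecomposition
of A reduces the ML log-likelihood to a 1-D profile in h, maximized on a
101-point grid refined by bounded Brent search to 1e-6 in h².  The grid is
linear in h² (rather than logarithmic in the variance ratio) because h² is
the bounded quantity of interest; the refinement tolerance is the same.
Boundary solutions (h² = 0 or 1) are allowed and flagged.  ML is the
default because that is the stated estimator for this design; REML is
available behind a flag.  Animal-level fitting (rather than line means)
uses every observation and makes σ²_e a combined within+between residual;
the suite verifies the profile against a brute-force 2-D Cholesky
likelihood grid (agreement <0.02 in h²), recovery of a true h² = 0.75 to
±0.05, and a null rate of ĥ² ≤ 0.05 in ≥90% of no-signal replicates.

Broad-sense H² uses one-way ANOVA over lines: V_e = MS_within,
V_g = (MS_between − MS_within)/n̄ with n̄ the arithmetic mean number of
animals per line, H² = V_g/(V_g+V_e).  Negative V_g (possible when lines
do not differ) is clamped to zero and flagged.  When every animal is
identical, H² is reported as 0.

Both estimators are reported for the raw trait and for the
corrected-then-normalized trait, in that order.

## Phenotype processing

Correction is an animal-level OLS of the trait on age (numeric) and batch
and origin (treatment-coded categoricals); residuals (mean zero) replace
the values and missing animals stay missing.  Constant covariates are
dropped as uninformative; a genuinely singular design (e.g. one batch per
animal) raises an error naming the offending factor.  Normalization is
the rank-based inverse-normal transform with Blom offsets,
Φ⁻¹((rank−0.375)/(n+0.25)), average ranks for ties; a constant trait maps
to all zeros with a warning.  The provenance chain raw → corrected →
normalized is enforced by the `TraitVector` type, so normalization cannot
precede correction.  Whether correction should be fitted on animals or on
line means is a genuinely open choice; animal-level was chosen to use all
observations, and correction is idempotent on its own output.

## QTL scan

The scan operates on weighted line means (weights = animals per line).  At
each interval, WLS regresses means on an intercept plus seven free founder
columns (one founder dropped as reference; probabilities sum to one so the
eighth column is redundant).  Founders absent from an interval across the
whole panel are dropped with a per-interval flag, and any remaining rank
deficiency is absorbed by a rank-revealing pivoted QR, which also sets the
F-test's numerator degrees of freedom.  LogP = −log₁₀ P is capped at 300
to avoid infinities.  A deliberate property: the scan contains no kinship
or covariate term — phenotypes are corrected upstream — so heritable
polygenic-only traits show visible inflation; the permutation threshold,
not the pointwise P, carries genome-wide error control.

Permutations shuffle line means across lines while weights stay attached
to their lines; each permutation's genome-wide maximum LogP is recorded.
The threshold at level α is the empirical order statistic at
⌈(1−α)·n_perm⌉, and an observed peak's permuted P uses the add-one rule
(1 + #{perm max ≥ observed})/(n_perm + 1), so the smallest attainable P is
1/(n_perm+1).  Support intervals are the maximal contiguous run on the
peak's chromosome with LogP ≥ peak − 1.  Per-interval designs are factored
once and reused across all permutations, which makes the 200×200
calibration study run in seconds.

## Annotation

Gene–interval overlap uses 0-based half-open coordinates, requiring ≥1 bp
of overlap, strand ignored.  Enrichment asks whether a QTL's genes sit at
implicated (low) positions of a supplied genome-wide ranking: the default
is a one-sided Mann–Whitney rank-sum of member ranks against all other
ranked genes; a resampling alternative draws random same-size gene sets
from the whole ranked genome (the background is all ranked genes, not
genes in QTLs) and reports an add-one tail probability of the mean rank.
The two routes agree within Monte-Carlo error and the rank-sum P is
calibrated uniform under random gene sets.  Ortholog mapping and curated
disease-gene lookups are inputs, not computations.

## Problem sizes and determinism

Default study conditions mirror a realistic CC behavioral study: ~50 lines,
5–6 animals per line, genome split into ~500–11,000 intervals.  The test
suite and the acceptance script use 400 lines for founder-share symmetry,
200 replicates × 200 permutations (50 lines, 500 intervals) for threshold
calibration, 50 replicates (100 lines × 5 animals) for heritability
recovery and null checks, and 50 replicates for QTL localization — sizes
chosen so each check carries tight Monte-Carlo error while the whole suite
runs in minutes.  All randomness flows through seeded NumPy generators;
panel-level operations spawn independent child seeds per line, and the
pipeline derives one child seed per stage from the config seed, so
identical configs give byte-identical outputs and manifest checksums.

## Known limitations

Haploid 8-state reconstruction cannot represent true heterozygous calls
except as ambiguity; X-chromosome transition models, parental-origin
phasing, multi-QTL/composite mapping, epistasis scans and dominance
variance components are not implemented.  The ANOVA H² interpretation
bundles epistatic with additive between-line variance by construction.
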
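# Methods

## Scope and model

`ldphasekit` estimates two-locus linkage disequilibrium from unphased
diploid genotypes, summarizes its decay with distance, correlates signed
LD phase across populations, and converts distance-binned r² into an
effective-population-size (Ne) trajectory. A forward Wright–Fisher
simulator supplies multi-breed panels with known demography; all
validation is against that ground truth or against independent oracles
(enumeration, grid search, closed forms).

## Haplotype frequency and LD from unphased genotypes

For loci with counted alleles A and B, only the double heterozygote is
phase-ambiguous. Assuming random union of gametes (Hardy–Weinberg at the
haplotype level), the likelihood of the 3×3 joint genotype table is
multinomial in the four haplotype frequencies, of which only f(AB) is
free once the allele frequencies are fixed by the margins. EM splits the
double-heterozygote count by the odds f(AB)f(ab) : f(Ab)f(aB) and
recounts haplotypes.

Numerical choices:

- **Multi-start.** The score equation in f(AB) is cubic; the likelihood
  can have two local maxima, and the natural linkage-equilibrium start
  f(A)f(B) can sit exactly on a symmetric saddle. EM therefore runs from
  the equilibrium start plus starts at 2% and 98% of the admissible
  interval [max(0, f(A)+f(B)−1), min(f(A), f(B))], keeping the solution
  with the highest likelihood. Tables invariant under flipping one
  locus's alleles have two exactly tied maxima (the sign of D is then
  unidentifiable); tests accept either.
- **Convergence**: |Δf(AB)| < 1e−10, at most 1000 iterations.
  Non-converged pairs are emitted flagged and excluded from phase and Ne
  summaries by default.
- **Pairs**: within-chromosome only, distance ≤ 10 Mb by default, and at
  least 30 individuals non-missing at both loci (pairwise-complete);
  smaller r² samples are badly biased. Pairs monomorphic among the used
  individuals are skipped.

D, r², and r = sign(D)·√r² follow algebraically. Flipping the counted
allele at one locus negates D and r and preserves r²; the counted-allele
orientation of every marker is therefore written to a JSON sidecar by the
PLINK-text writer and re-applied on read, and cross-population matching
sign-corrects (or rejects) pairs whose orientation differs.

## Marker QC

Three per-marker filters in fixed order (each removed marker is
attributed to the first filter it fails): call rate < 0.95, exact
conditional Hardy–Weinberg test p < 0.01, MAF < 0.05. Boundaries follow
the stated rules: a marker at exactly 95% call rate or exactly 5% MAF is
retained. The HWE test conditions on the observed allele counts and sums
the probabilities of all heterozygote counts no more probable than the
observed one; monomorphic markers get p = 1 (and are removed by the MAF
filter instead). A chi-square variant is available for comparison. QC is
applied within each population separately, since LD analyses are
per-population and a marker can be clean in one breed and distorted in
another.

## Decay summaries and the decay regression

Distances use 1-based bp positions; one Morgan = 10⁸ bp. Two stock bin
schemes: a fine scheme (first bin [0, 10 kb), then 5-kb bins to 5 Mb,
pairs restricted to the first 5 Mb of each chromosome) and a coarse
scheme (0–30, 30–70, 70–100, 100–200, 200–1000 kb). All intervals are
half-open [lo, hi) because printed "0–30 kb"-style labels are ambiguous
at their boundaries. Summaries report mean and SD of r² and the share of
pairs with r² strictly > 0.3 (configurable to ≥); useful-LD coverage
uses ≥ 0.15 over adjacent-in-map pairs within 70 kb ("at least" is
inclusive).

The decay model is ordinary least squares on per-pair records — r² on
distance (continuous covariate) with population and chromosome as crossed
factors plus their interaction. The ANOVA table is sequential (type I) in
the order population, chromosome, distance, interaction, computed by
nested model comparison so the term order is exact even with a continuous
covariate among factors. Factor terms with a single level are dropped;
rank-deficient designs (e.g. population confounded with chromosome) are
reported as errors rather than silently absorbed.

## Phase persistence

Records from two populations are inner-joined on the marker pair; the
Pearson correlation of (r_A, r_B) is reported per distance stratum
(default 0–70, 70–100, 100–200 kb, half-open). The high-LD restriction
keeps pairs with r² ≥ 0.3 in *both* populations by default — the
restriction's one-sided variants are available by flag, since either
convention is defensible and the choice matters for the reported value.

## Ne estimation

Sved's E[r²] = 1/(1 + 4·Ne·c) is inverted at the mean r² of pairs whose
c lies within a multiplicative window (×/÷ 1.1 by default) of the target
c = 1/(2g) for each requested generation g. The representative c of a
window is the mean c of its contributing pairs (not the window midpoint),
and the reported age is 1/(2c) at that representative c. A minimum-c
floor of 1e−5 Morgans guards the inversion. Observed r² from n sampled
chromosomes is inflated by ≈ 1/n even at linkage equilibrium; the
optional sample-size correction subtracts 1/n from the bin mean before
inversion. It is **off by default** (the plain formula) but **on** in the
recovery experiments and the demo trajectory, where full sampling of a
small population makes the inflation comparable to the drift signal.
Hill's demographic formula Ne = 4NL/(2 + σ²_n) is provided for converting
census counts, generation length, and family-size variance.

## The simulator and what it does (not) emulate

Discrete-generation Wright–Fisher: random union of gametes, selfing
allowed, piecewise-constant diploid N per population. Recombination has
no interference — each inter-marker interval crosses over independently
with probability min(Δbp/10⁸, 0.5), capped at free recombination since a
Bernoulli probability cannot exceed ½. There is no mutation: founder
variation (per-locus frequencies Uniform(0.1, 0.9), haplotypes initially
in linkage equilibrium) is the only source of polymorphism, which is
adequate at LD-decay timescales and keeps allele bookkeeping trivial but
means long simulations lose polymorphism to fixation. Chip-style
ascertainment (drop sample-MAF < 0.05, mask genotypes at random) is
applied at export, which mimics commercial SNP panels and gives the QC
filters realistic work.

The default study design mirrors a two-breed-plus-crossbred beef-cattle
setting at desk scale: 3 chromosomes × 500 markers at ~70 kb mean
spacing (the mean adjacent-marker distance of a 50k bovine chip), a
common ancestor of N = 1000 burned in 300 generations, a split 250
generations ago followed by decline from 1000 to 250 in each breed
(an illustrative schedule, not a reconstruction of any real breed
history), sampled cohorts of 597, 450 and 616 (the last an F1 cross),
1% missing genotypes. When a sampled cohort exceeds the final breeding
population, one extra generation at the cohort size is bred — a census
far larger than Ne, as in livestock.

What passing the simulation tests does *not* show about real data: no
ascertainment toward intermediate MAF beyond the floor, no genotyping
error, no pedigree structure or non-random mating, no selection, no
variation in recombination rate along the genome, and crossbreds are
exact F1s rather than the mixed-composition animals of real herds (an
F1 panel fails HWE at strongly diverged markers by construction, so QC
removes more markers there than it would in a mixed pedigree).

## Validation experiments and problem sizes

- **Ne recovery**: constant N = 100, 3 chromosomes × 350 markers over
  10 Mb, 300 burn-in generations, all individuals sampled, correction on;
  bins at generations 40–400 (4Nc between 0.5 and 5, where the Sved
  relation is informative). The median across 5 seeds sits within a
  factor of 2 of the truth in every bin.
- **Phase persistence vs divergence**: base N = 200 split into two
  N = 200 lines, snapshots at 10/100/500 generations, 2 chromosomes ×
  600 markers over 6 Mb (dense enough to populate the 0–70 kb stratum
  after fixation losses). Because fixation and ascertainment change
  which pairs remain estimable over time, all snapshots are compared on
  the common set of estimable pairs — otherwise composition drift
  confounds the time trend. An F1 cross at generation 100 checks that
  parent–crossbred phase correlation is at least the parent–parent one.
- **Decay regression**: planted r² = 0.3 − 0.5·d(Morgans) + N(0, 0.01²)
  recovers the slope within 3 SE; the sequential ANOVA sums of squares
  add to the total corrected SS to ~1e−16 relative error.

These sizes were chosen so the full suite runs in minutes on one CPU
while each check retains clear statistical power; they are stated here
as the package's reference conditions.

## Known limitations

- EM under random union of gametes is the genotype-based estimator;
  family- or pedigree-phased haplotypes would give slightly different r
  near the phase-unidentifiable boundary.
- The Sved inversion is biased where 4Nc is far outside [0.5, 5] and
  where demography changed rapidly within a window's time horizon; the
  trajectory is a smoothed, model-based summary, not an estimator with
  per-point standard errors.
- Signed-phase comparisons require a shared counted-allele orientation;
  panels lacking orientation metadata are joined on the assumption that
  orientations agree.
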
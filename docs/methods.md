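# Methods

## Model

`segshare` treats relationship identification as a discrimination
problem on observed IBD sharing. All results are conditional on three
assumptions: sharing is **uniparental** (one common ancestor or founder
couple on one side of each individual's pedigree; at most one allele
shared per locus), founders and in-marrying mates are unrelated and
non-inbred, and shared segments are observed without error. Autosomes
only; crossovers follow the Haldane model — counts Poisson with mean
equal to the map length in Morgans, positions uniform, no interference.
Under these assumptions the set of segment numbers, end-positions and
lengths is *all* the information the genome carries about the pedigree,
so the computed discriminating power is an upper bound for real data.

### Gene dropping

Founder haplotypes are single-interval mosaics with globally distinct
integer labels; each meiosis samples crossovers, picks the starting
parental haplotype with probability 1/2, and alternates source at every
crossover. Unrelated mates introduced along a lineage receive fresh
labels per pedigree instance, which makes spurious sharing impossible by
construction. A pair shares a position IBD iff some haplotype of one and
some haplotype of the other carry the same founder label there; maximal
shared intervals are positional, so segments inherited through the two
haplotypes of a diploid elder (an uncle, a lineal ancestor) merge. That
merging is exactly what gives avuncular and lineal pairs different
segment-count distributions from cousin-type pairs of the same *R*
(e.g. E(*n*ₛ) = (5*l* + 2)/4 for uncle–nephew instead of the collateral
formula).

The catalog's 19 relationships are parameterized by family base and the
meiosis counts (g₁, g₂) from the founders to each tracked endpoint;
Wright's numerator relationship is *R* = a(½)^(g₁+g₂) for collateral
pairs (a = 2 for a full-sib base) and (½)^d for lineal chains of d
meioses. Endpoints with g = 1 on the full-sib base (the uncle) and
lineal ancestors are diploid; every other endpoint is tracked through
the single haplotype descending from the shared ancestry.

### Two simulation paths

The object layer (`meiosis`, `relationships`) implements meioses and
pedigrees literally, one replicate at a time. The batch engine
(`engine`) exploits the fact that each meiosis is a two-state telegraph
process along the chromosome and that the sharing indicator is a boolean
function of the relevant processes; pooling all crossover events of a
batch and sorting once turns 10⁵ replicates into a handful of flat numpy
passes. The two paths are distributionally identical; the test suite
verifies this by chi-square on (*n*ₛ, *p*ₛ) outcomes for avuncular,
half-sib-base and lineal representatives. All production distribution
estimates use the engine.

A replicate's outcome is reduced to *n*ₛ (segment count), *p*ₛ (ends of
the chromosome covered: 0, 1 or 2) and the total shared proportion,
discretized into tenths *t*ₛ ∈ {1, …, 10} by the half-open rule
(t−1)/10 < x ≤ t/10. Conditional segment sub-lengths are discarded: for
fixed (*n*ₛ, total) the split of length between segments is uniform and
carries no pedigree information (verified by a KS test). Outcome keys
use all three components for 1 ≤ *n*ₛ ≤ 4 but drop *t*ₛ for *n*ₛ > 4,
where cells would be too sparse to estimate and would mostly add
simulation noise.

## Likelihood machinery

Probabilities P_R(k) are replicate proportions (multinomial MLE),
treated as known when computing moments. Log-likelihood ratios use
natural logarithms. If one hypothesis's estimated probability is exactly
zero while the other's is positive, the zero is replaced by 1/(2N); the
number of such substitutions is logged, and at N = 10⁵ it is zero or
near-zero for all tabulated pairs, mattering only where E(λ) is already
very large. An outcome unseen under *both* hypotheses contributes 0 with
a logged warning.

Chromosomes segregate independently, so per-chromosome cumulants of λ
under the true distribution add across the genome: κ₁ (the directed
Kullback–Leibler distance), κ₂, κ₃ and κ₄ = μ₄ − 3μ₂² are accumulated
per length class and weighted by chromosome counts; skew = κ₃/κ₂^{3/2}
and excess kurtosis = κ₄/κ₂² (the excess convention is used and labeled
explicitly). Both are small for genome-wide λ, supporting the normal
approximation Φ(−E(λ)/SD(λ)) for the misclassification probability of
the sign rule.

Assignment experiments draw fresh genomes from a random stream
independent of the one that estimated the distributions (held-out
evaluation, avoiding the optimistic bias of scoring training
replicates); exact ties λ = 0 count one half, which is unbiased under
the symmetric null.

The Poisson-approximate likelihood replaces the simulated count
distribution by Poisson pmfs whose means come from the closed forms,
while expectations are still taken under the simulated truth
distribution — quantifying what the (false) Poisson assumption costs:
for uncle–nephew vs half-sib on 22 equal chromosomes the expected ratio
drops from ≈ 1.8 to ≈ 0.8 nats.

## Genome models and problem sizes

Built-in models: `human5` (2 × 0.75, 8 × 1.25, 6 × 1.75, 4 × 2.1,
2 × 2.75 M; 22 autosomes totaling 35.9 M), `equal22` (22 × 1.632 M, the
same average length), and `many72`/`few12` (36 M split into 72 × 0.5 M
or 12 × 3 M) for studying chromosome-number effects. User models are
YAML lists of (length, count); lengths are Morgans internally, with cM
accepted at I/O boundaries.

Default problem sizes follow the study conditions the tables were
computed under: 10⁵ replicates per (relationship, chromosome length) for
distribution banks and single-chromosome moments, 3 × 10⁵ for the
equal-length Poisson comparison, and 10⁴ held-out genomes per
relationship in assignment experiments. At these sizes single-chromosome
count means carry a Monte-Carlo SE of ~0.003 and genome-wide E(λ)/SD(λ)
reproduces across independent runs to ~1–2%.

## Numerical choices

- Positions are real-valued doubles; no grid. Coincident crossover
  positions within a meiosis (measure zero) are resolved by resampling
  in the object layer and are statistically immaterial in the engine.
- End-touching for *p*ₛ compares stored breakpoints to 0 and *l*
  exactly, no epsilon; a single segment covering both ends forces
  total = 1 exactly (run boundaries are the exact floats 0 and *l*).
- *t*ₛ boundary ties use exact ≤ on floats; the convention is documented
  for bit-reproducibility and is measure-zero in effect.
- Distribution banks are keyed by (relationship, rounded cM) and
  round-trip through tab-separated files bit-exactly; every output
  header records seed, N, genome and version, and identical
  configurations reproduce outputs byte for byte.
- All randomness flows through explicit `numpy.random.Generator`
  streams.

## What the generator does and does not emulate

The simulator reproduces Mendelian segregation and Haldane recombination
for idealized pedigrees with error-free segment observation. It does not
model segment-detection error (short segments are the most likely to be
missed in real data, biasing relationship estimates downward), crossover
interference or sex-specific maps, background/population relatedness,
inbred ancestors, bilateral sharing (full sibs, double cousins), or the
X chromosome. Passing tests therefore certify the inference machinery
and the theoretical limits it computes, not performance on segments
called from noisy genotype data.

## Design notes

- The avuncular great-uncle pair is parameterized as full-sib-base
  (1, 3); half-great-uncle–great-nephew is not a separate catalog entry
  because its sharing distribution is identical to half-cousins — the
  suite asserts this equivalence (and the corresponding full-sib-base
  *in*equivalence) rather than duplicating a row.
- The collateral count formula is applied with d = g₁ + g₂, a = 2 to
  *all* non-avuncular full-sib-base pairs including asymmetric ones
  (cousins once removed etc.); the suite checks it against simulation
  for the whole catalog rather than asserting a validity boundary.
- Each relationship is simulated independently rather than re-scoring
  one pedigree instance for several relationships; the engine makes the
  extra cost negligible and estimates stay uncorrelated.
- Moment aggregation across chromosomes uses cumulant additivity; for
  mean and variance this is plain summation, and it is the standard
  identity for skew and kurtosis of independent sums.

## Known limitations

Discrimination figures are upper bounds under error-free observation.
Empirical distributions are plug-in estimates; extreme tail cells of λ
depend on the 1/(2N) convention. The normal approximation for
misclassification degrades for very distant pairs where E(λ)/SD(λ) is
small and skew relatively larger. Observed-pair classification assumes
segment coordinates already in genetic map units.
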
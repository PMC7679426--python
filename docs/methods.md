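# Methods

`hexassr` analyses microsatellite (SSR) fingerprints of polyploid,
clonally propagated germplasm in which allele dosage is unobservable.
This note documents the statistical model behind each stage, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions.

## Dosage-blind genotypes

Capillary electrophoresis of a polyploid individual reveals *which*
allele sizes are present at a locus, not *how many* of the ploidy gene
copies carry each one.  A call is therefore an **allele phenotype**: a
set of 1..ploidy distinct integer fragment sizes.  All downstream
statistics either (i) count each observed allele once per individual
("one per phenotype") or (ii) integrate over the unobserved dosage.

### Allele binning

Raw fragment sizes are fractional.  True alleles of one SSR differ by
whole repeat motifs, i.e. lie on a grid `offset + motif_length · k`.
`bin_alleles` searches offsets exhaustively in 0.1 bp steps over one
motif period, keeps the grids that map every raw size to an integer with
displacement strictly inside the instrumental resolution (±1 bp by
default), and picks the grid with the smallest mean absolute
displacement.  Ties go to the grid that rounds sizes down on balance
(smaller signed mean displacement), then to the smaller offset — a
deterministic convention.  A raw size displaced by the full resolution
is indistinguishable from the neighbouring grid point, so such inputs
are rejected with the offending sizes listed rather than silently
snapped; this is the conservative choice for instrument-limited data.

### EM dosage correction

For frequency-based indices, dosage matters.  The `EM_DOSAGE` estimator
assumes each individual's ploidy gene copies are independent draws from
the population allele frequencies (a Hardy–Weinberg-like completion
prior conditional on the observed allele set).  For a phenotype with
alleles `S`, the possible dosages are the compositions of the ploidy
into |S| positive parts; the posterior weight of dosage `d` is
proportional to `multinomial(d) · ∏ f_a^{d_a}`.  EM iterates expected
copy counts → frequency update, initialized deterministically at the
one-per-phenotype frequencies, until the largest frequency change is
below 1e−10 or 1000 iterations.  At hexaploid ploidy the composition
count is at most 10 per phenotype, so the E step is exhaustive, not
sampled.  The alternative completion priors that dosage-correction
software might use are not documented in the genotyping literature this
package follows; both estimation modes are exposed so users can compare.

## Per-locus indices

With `p_i` the allele frequencies and `N` the gene-copy count:

- **1-D** (Simpson's index of diversity): `1 − Σ p_i²`.
- **En** (effective number of alleles): `1 / Σ p_i²`; `1 − 1/En = 1-D`.
- **Ev** (evenness): `[(1/λ) − 1] / [e^H − 1]` with `1/λ` Stoddart and
  Taylor's index and `H` Shannon diversity; 1 for uniform frequencies,
  NaN (0/0) for a monomorphic locus.  Computed from allele frequencies;
  a genotype-abundance variant can be obtained by feeding a
  genotype-frequency spectrum to the same function.
- **AR** (allelic richness): hypergeometric rarefaction
  `Σ_i [1 − C(N−N_i, k)/C(N, k)]`, the expected distinct-allele count in
  a subsample of `k` gene copies.  `k` defaults to the smallest
  per-locus copy count within the marker class, so missing data never
  make a locus incomparable.
- **GD** (gene diversity): Nei's unbiased `N/(N−1) · (1 − Σ p_i²)`.
- **Ho**: fraction of individuals showing ≥ 2 distinct alleles.
- **GH** (gametic heterozygosity): mean over individuals of the
  probability that two gene copies drawn without replacement from the
  individual differ, `1 − Σ_a C(d_a,2)/C(ploidy,2)` for dosage `d`,
  averaged over the EM dosage posterior (default) or computed at equal
  fractional dosage (`ONE_PER_PHENOTYPE` shortcut).
- **Hs** (expected heterozygosity with dosage correction): GD computed on
  the EM-dosage spectrum, `N = ploidy × non-missing samples`.
- **R = En/An** and its z-test: within a marker class,
  `z_i = (R_i − mean R)/sd(R)` with the sample sd, two-sided p from the
  standard normal.  This flags loci whose frequency spectrum is
  unusually skewed for their class.  The normal reference is a
  descriptive convention (the class holds only ~5 loci); the construction
  is deliberately simple and documented rather than inferred.

An, 1-D, Ev, AR, GD and En use the one-per-phenotype spectrum (the
dosage-agnostic convention of polyploid SSR reports); Hs and GH use the
EM correction.

## Genotype accumulation

For subset sizes 1..L−1, locus subsets are drawn without replacement
(10 000 resamples by default, seeded) and the number of distinct
multilocus genotypes (MLGs) counted.  Missing calls compare equal by
default — the conservative choice, since treating missing as a wildcard
inflates apparent discrimination; a flag switches to unique-missing.
Internally phenotypes are integer-coded per locus and subsets hashed in
mixed radix, so each resample costs one vectorized sort.

## Bruvo distance

Alleles are converted to repeat units (size / motif length).  The
per-allele distance is `1 − 2^(−|x−y|)`, a geometric kernel under which
one-step mutations are close and far alleles saturate at 1.  The
genotype distance is the minimum over assignments of one phenotype's
alleles to the other's of the mean per-allele distance.  At hexaploid
scale the assignment is solved by vectorized exhaustive permutation
(≤ 720 bijections), which is exact; the test suite checks it against an
independent nested-loop enumeration.

Phenotypes of unequal size are handled by four models: `INFINITE`
(virtual alleles at distance 1), `GENOME_ADDITION` (augment the smaller
phenotype with copies of its own alleles, average over every ordered
choice, each optimally assigned), `GENOME_LOSS` (augment with alleles of
the larger phenotype), and `COMBINATIONAL` — the mean of addition and
loss — which is the default, appropriate when neither chromosome gain
nor loss can be assumed for a polyploid of unknown history.  Ordered
fills are enumerated as weighted multisets, so the worst hexaploid case
(6^5 ordered fills) costs 252 assignments.  Multi-locus distance is the
mean of per-locus distances over the loci at which both samples have
calls; a pair with no comparable locus is an error rather than an
imputed value.  Distances are computed per marker class and never
pooled, since the two classes are the objects being compared.

## Trees and matrix comparison

**UPGMA** uses the cluster-size-weighted average-linkage update; merge
height is half the merge distance, so the tree is ultrametric with
leaves at height 0.  Ties are broken toward the pair containing the
lexicographically smallest member label, making trees reproducible.  On
an already-ultrametric matrix the cophenetic matrix of the output equals
the input exactly.  Newick branch lengths are height differences.

**Cophenetic distance** of two leaves is twice the height of their
lowest common ancestor.

**Mantel test**: Pearson correlation of the off-diagonal upper
triangles; the null distribution permutes one matrix's labels jointly
over rows and columns (the standard single-matrix permutation), with
`p = (#{r* ≥ r} + 1)/(n_permutations + 1)`.  One-sided (greater) by
default, matching the directional question "do the two marker classes
rank pairs similarly"; two-sided available.  Permutations are fully
vectorized and seeded.  Tree comparison runs Mantel on the two
cophenetic matrices and emits the aligned leaf orders — the textual
replacement for a tanglegram.

## Class comparison

Welch's t-test by default (no variance pooling assumption across marker
classes; pooled available by flag).  CV = 100·sd/mean with a selectable
denominator, because both the population (N) and sample (N−1)
conventions occur in the literature this package mirrors — reproducing
published CVs requires knowing which was used.  Normality is checked
with a one-sample Kolmogorov–Smirnov test against a normal with the
sample mean and sd; estimating parameters from the data biases this
test conservative (the Lilliefors caveat), which is documented rather
than corrected because the package mirrors common genotyping practice.

## Synthetic germplasm generator

Defaults emulate the reference design: 44 hexaploid varieties × 2
plants, 5 EST-SSR loci with 6–12 alleles (trinucleotide) and 5 genomic
SSR loci with 14–26 alleles (dinucleotide).  Per locus, an allele pool
of contiguous motif-grid sizes anchored at a random 100–250 bp base
receives Dirichlet(0.3) frequencies.  The concentration is calibrated
against the panel-level estimator rather than the generative truth:
dosage-blind one-per-phenotype counting flattens skewed spectra (each
allele counts once per carrier regardless of copy number), so the
generative skew must be stronger than the target spectrum suggests.  At
0.3 the panel-level mean R = En/An sits near 0.55 (replicate range
roughly 0.3–0.85), inside the 0.2–0.6 band that dosage-blind SSR panels
typically show on average.  Each
variety draws its 6 gene copies multinomially; clone mates copy the
variety genotype, with a 2 % per-locus chance of a single ±1-motif
stepwise mutation (the microsatellite-appropriate mutation mode, which
also exercises the geometric Bruvo kernel) and a 3 % per-call no-call
rate.  Scoring is dosage-blind.  The truth record keeps frequencies,
dosages and the clone map.

What the generator does **not** emulate: linkage between loci, null
alleles and allele-specific amplification failure, stutter or sizing
error (inputs are assumed binned), population structure among varieties,
and any hybridization history.  Passing tests therefore validate the
estimators under the stated sampling model, not robustness to these
artefacts.

## Problem sizes and seeds

All randomness flows from one master seed through named
`SeedSequence` substreams, so every output is reproducible from the run
manifest.  Validation checks use: EM-recovery at 500 independent samples (±0.02
tolerance, the sampling-theory scale of Hs error at that size), Mantel
null calibration over 1000 matrix pairs at 99 permutations (the
rejection rate at α = 0.05 must land in [0.03, 0.07]), and the
EST-vs-genomic ordering over 100 default-configuration replicates.  The
acceptance script uses 50 ordering replicates and 500 null pairs, sizes
at which the binomial error of the reported fractions is ~2 %.

## Known limitations

- The EM dosage model assumes independent gene copies; inbreeding or
  double reduction would bias Hs in ways the generator does not probe.
- The rarefaction formula needs integer counts, so AR is always computed
  on the one-per-phenotype spectrum, whose "gene copy" unit is an
  observed-distinct-allele count rather than a true chromosomal count.
- The R z-test treats ~5 loci as a normal sample; its p-values are
  indicative, not calibrated.
- Bruvo model enumeration is exact only for ploidy ≤ 6; higher ploidies
  would need the Hungarian algorithm and sampled fills.
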
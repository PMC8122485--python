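# Methods

Models, algorithms, default parameters and numerical choices, module by
module. Coordinates are 1-based base pairs (`pos_bp`, the VCF
convention) everywhere except the BED-like introgression tracks, which
are 0-based half-open.

## Breeding-design simulation (`simcore`)

**Meiosis.** Crossovers per chromosome are Poisson with mean
length_cM/100 (Haldane model: no interference), breakpoints uniform on
the genetic map; a gamete is assembled by switching between the two
parental haplotypes at the breakpoints. Founders are fully homozygous,
so a haplotype is represented as a vector of founder-of-origin indices;
allele states are looked up from the founder panel only at genotyping
time.

**Pedigree.** `advance_family` implements exotic × reference → F1;
F1 × reference → BC1F1; then three generations of single-seed-descent
selfing to BC1F4. BC1F4:6 seed bulking adds no further meioses, so the
BC1F4 genotype is the line genotype. Expected consequences, used as test
oracles: exotic genome share 1/4; heterozygosity at parent-polymorphic
loci (1/2)·(1/2)^3 = 1/16.

**Culling.** Optional BC1F2 culling is rejection-and-redraw: a candidate
BC1F2 whose genetic value for any culled trait falls outside its
`(low, high)` window is discarded and the family's BC1F1 produces a new
selfed seed, up to `max_retries` (then `CullingError`). Culling acts on
the genetic value only (no plot noise at culling time).

**Genotyping.** Codominant markers report both alleles; dominant markers
collapse to presence/absence of the first reference parent's allele.
Missing calls are i.i.d. Bernoulli per (line, SNP). With
`het_preserved=False` heterozygous calls are masked to missing instead
(a conservative-caller mode).

**Trials.** `rcbd_design` replicates every line once per complete block;
`prep_design` replicates a subset plus checks twice. Plot values are
intercept + genetic value (heterozygotes score the mean of the two
allele effects) + block effect + i.i.d. residual; `residual_sd` may vary
by trial.

**Realism limits.** No crossover interference, no mutation, no
segregation distortion, no selection other than explicit culling, field
error is i.i.d. (no spatial autocorrelation surface; row/range can enter
the REML model as independent random factors instead).

## Marker construction (`markers`)

**SNP missingness filter.** Strictly more than 40% missing (codominant)
or 20% (dominant) removes the SNP.

**LD.** r² is the squared Pearson correlation of 0/0.5/1 dosages over
pairwise-complete lines, computed by masked matrix algebra; zero-variance
columns yield NaN (never grouped).

**Tagging.** Eligible SNPs (MAF ≥ 0.01, missingness ≤ 0.06, within a
genetic background's lines) are linked when r² ≥ 0.7 and their distance
is within a 10,000 kb window; groups are the transitive closure
(union-find) of these links. Tagging runs per genetic background
(reference-parent subpopulation) and the per-background groups are
merged across backgrounds (`merge_tag_groups`, again transitively). A
group is named by its leftmost member: `LDB_<chrom>_<bp>`.

**Haplotype markers.** A marker's allele dictionary maps the
concatenated member-SNP allele string to a 1-based index in order of
first observation, scanning parent rows before progeny so parental
haplotypes get the smallest indices. A line's call is defined when at
most one member SNP is heterozygous — the two local haplotypes are then
unambiguous, and exactly-one-het lines produce heterozygous marker calls
(which makes the downstream 6% marker-heterozygosity filter meaningful);
two or more het members give a missing call, as does any missing member.
Monomorphic and all-missing markers are dropped with counts logged.

**LD-kNN imputation.** For a missing call, the `l` = 30 SNPs with
highest r² to the target SNP define a line-to-line distance; the `k` = 5
nearest lines with an observed call vote for their genotype with weight
1/distance. Ties break deterministically toward the smaller genotype
code, so imputation is reproducible.

**Marker/line quality filter.** Markers with call rate < 70% or
heterozygosity > 6% are removed first; then lines called at < 50% of the
surviving markers are removed. Removing everything raises rather than
returning an empty set.

## Population structure and introgression (`popstruct`)

**GSC.** Per locus, two unordered diploid genotypes score shared-alleles
/ 2 (1, 0.5 or 0, computed as max over the two pairings); the pairwise
GSC is the mean over loci called in both lines (pairwise complete, NaN
and a warning when a pair shares no locus).

**Eigenstructure.** NaN entries are imputed to column means and the
matrix re-symmetrized; the matrix is double-centred (H G H) and
decomposed with `eigh`. Percent variance is each eigenvalue over the sum
of positive eigenvalues.

**Introgression.** For each family, informative loci are those where
both parents are homozygous, called, and different. A RIL's carrier
score at such a locus is the fraction of its two alleles matching the
exotic parent (0, 0.5, 1). Frequencies pool carrier scores across
families sharing a reference parent; the genome-wide mean pools over all
informative (line, locus) calls. Tracks assign each marker the interval
between midpoints to its neighbours, truncated to gap_bp/2 = 5 Mb per
side; marker-free stretches beyond that are emitted as `gap` rows.
Frequencies ≥ 0.25 are flagged `high`.

## REML, BLUPs and heritability (`phenostats`)

The per-trial model is y = μ + genotype + block (+ row + range) with all
non-intercept terms independent random effects. The restricted
likelihood is profiled over the residual variance, leaving only the
log10 variance ratios, which are optimized by coordinate-wise bounded
golden-section search (`minimize_scalar`, bounds ±8, xatol 1e-10),
sweeping until the −2·REML log-likelihood changes by < 1e-8. Z Zᵀ per
term is precomputed once per fit; each likelihood evaluation is one
Cholesky of the n×n profiled covariance. Ratios at the search floor are
reported as zero variance. BLUPs and the full prediction-error-variance
(PEV) matrix come from the mixed-model equations at the optimum.

Generalized heritability (Cullis) is
H² = 1 − mean PEV of pairwise line differences / (2 σ²g), clamped to
[0, 1] and defined as 0 when σ²g ≤ 0. For a balanced RCBD this
approaches σ²g / (σ²g + σ²e/r), which the tests use as a closed-form
oracle.

`selection_summary` reports the fraction of candidate lines whose
maturity BLUP lies inclusively between two named check varieties and the
fraction strictly below a height cap; checks are excluded from the
candidates and a missing check raises.

## Association scan (`assoc`)

**Designs.** A marker with a alleles contributes a−1 dosage columns
(0/0.5/1; heterozygote 0.5); the reference allele is the most frequent.
Missing calls are mean-imputed per column. Markers monomorphic among the
analysed lines are skipped and logged. Only lines with role `ril`,
a BLUP and eigenvector coordinates enter.

**Stage 1.** Each marker is F-tested against the covariate-only model
(intercept + top 10 eigenvectors) with rank-based numerator degrees of
freedom; markers with p ≤ 0.0005 are preselected, sorted by p.

**Stage 2.** Forward selection adds the candidate with the smallest
partial p (ties break by chromosome, position, then id) while
p ≤ alpha; backward elimination removes the worst included marker while
its partial p given the others exceeds alpha; the loop runs to a fixed
point (outer iterations capped at 100). `bonferroni=True` divides alpha
by the stage-1 count. Each retained marker reports a type-III partial
R² = (RSS without it − full RSS)/total corrected SS × 100 and allele
effects from the full multi-locus fit, centred so the frequency-weighted
mean effect is zero (the reference allele's raw coefficient is 0).

**Anchoring.** Known genes attach by exact marker id, else by nearest
anchor on the same chromosome within `window_bp`.

## Files and pipeline (`io`, `pipeline`, `cli`)

Genotypes round-trip through VCF 4.2 text (GT only, `./.` missing,
synthetic nucleotide tokens, allele code 0 = REF); cM positions and
marker classes travel in a sidecar map TSV. Haplotype markers round-trip
through a definitions TSV (members + allele dictionary) and a calls TSV
(`.` missing, `i` homozygous, `i/j` heterozygous). The pipeline chains
simulate → markers → structure → introgression → blup → gwas over one
artifact directory; the manifest records the seed, the full
configuration and its sha256, per-stage summary counts and a sha256 per
file. Floats are written with a fixed `%.10g` format so identical seeds
give byte-identical artifacts. A failing stage persists the manifest
(with `failed_stage`) before re-raising.

Default thresholds throughout (overridable in `PipelineConfig`): LD
r² 0.7, MAF 0.01, tag missingness 0.06, 10,000 kb window, 40%/20% SNP
missingness cuts, 70% marker call rate, 6% marker heterozygosity, 50%
line call rate, kNN k=5 / l=30, alpha 0.0005, 10 eigenvectors.

## Testing approach

Every module is tested against independent oracles: hand-enumerated toy
matrices (filters, GSC, tracks), closed-form pedigree expectations
(0.25 exotic share, 0.0625 heterozygosity), a single-locus
rejection-sampling chain for culling, statsmodels as an external GLM
implementation for the scan, REML variance recovery and the balanced
heritability formula, planted-QTL recovery with a ±10 Mb evaluation
window, and byte-identity of pipeline reruns. The end-to-end statistical
checks in `tests/test_acceptance.py` run on fixed seeds with tolerances
stated next to the theory they test.
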
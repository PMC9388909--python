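# Methods

`polytome` analyses fraction-resolved polysome-profiling RNA-seq: total RNA
plus three ribosome-occupancy pools — monosomes (80S), light polysomes (2-4
ribosomes) and heavy polysomes (>4) — sequenced under two conditions (low
and high glucose) in replicate. The goal is to identify transcripts whose
*translation* changes while their steady-state abundance does not, to group
them by the shape of that change across pools, and to relate the groups to
mRNA sequence and structure features.

## Differential translation

Counts in each fraction are normalised to counts per million on that
fraction's own library sizes and transformed to log2(CPM + 0.5). Per gene
and per fraction an ordinary least-squares model with coefficients
(intercept, condition) is fitted; the contrast estimate is the log2
fold-change of high over low glucose. Residual variances s²_g (d = n − 2
degrees of freedom) are shrunk by empirical Bayes:

    s²_post = (d0·s0² + d·s²_g) / (d0 + d),      t̃_g = β̂_g / (s_post·su),

with t̃ referred to a t distribution on d0 + d degrees of freedom. The
hyperparameters (d0, s0²) are estimated by method of moments on log s²
using digamma/trigamma identities, with a Newton inversion of the trigamma
function; when the observed spread of log s² does not exceed the
chi-squared sampling spread, d0 = ∞ and every posterior variance equals the
common prior (the arithmetic mean of the variances). The plain
(single-prior) route agrees with the reference R implementation
(`limma::eBayes`) to machine precision on shared fixtures; the test suite
enforces this through an Rscript oracle.

By default the prior is *abundance-dependent*: log s² is smoothed on mean
log-CPM by lowess (span 0.4, 3 robustness iterations) and genes are shrunk
toward the trend value at their abundance. Log-scale variances of count
data fall with abundance; a single pooled prior under-estimates the
variance of low-count genes and inflates their moderated t, producing
spurious calls concentrated below ~50 CPM in null simulations. The trended
prior removes that inflation (raw-p fraction at the 5% threshold: 0.041 to
0.047 across 20 null cohorts, computed by the suite); `trend=False`
restores the plain squeeze.

P-values are adjusted by Benjamini-Hochberg step-up (Holm and BY are
available). A gene is called regulated at adjusted p ≤ 0.05 (inclusive) and
|logFC| > 0.5 (strict). Differentially translated genes (DTGs) are those
regulated in the light or heavy pools; total-RNA calls (DEGs) are computed
identically and are expected to be near-empty when regulation is purely
translational. Fractions are fitted separately by default because pooling
the error model across pools assumes equal residual variance there; an
option estimates one untrended prior on all fractions jointly.

## Translation ratio and efficiency

For fraction f ∈ {mono, light, heavy} and condition c, the translation
ratio is TR(f, c) = mean replicate TPM in (f, c) divided by mean total-RNA
TPM in c — a per-gene occupancy proxy that cancels transcript abundance.
Translation efficiency contrasts the light+heavy average A_c =
(TR(light,c)+TR(heavy,c))/2 between conditions: TE = log2(A_high/A_low),
oriented so positive TE means more translated in high glucose (a raw
difference mode and the opposite orientation are options). Genes are
classified UP (TE ≥ +0.5), DOWN (TE ≤ −0.25), CONTROL (|TE| ≤ 0.01),
otherwise UNCLASSIFIED; the labels partition the gene set. The UP boundary
is inclusive. "Most translated" rankings take, per condition, the max of
the light and heavy TR (configurable to the mean — the exact ranking
statistic is a free choice here), with ties broken by gene identifier.

The polysome/monosome ratio of an A254 gradient trace is the trapezoidal
area of the polysome window divided by that of the 80S window, each after
constant-baseline subtraction (per-window minimum by default; the baseline
rule is a package choice, not a community standard). A helper pools
14-fraction tables into the sequencing windows 5-6 / 7-9 / 10-13.

## Behaviour clustering

The clustering substrate is the genes × {mono, light, heavy} matrix of
log2 ratios of mean TPM, high over low glucose, restricted to DTGs (genes
with a zero mean in either condition are excluded and reported). Three
algorithms are compared:

- Ward hierarchical clustering on Euclidean distances (squared-distance
  Lance-Williams update, the Ward.D2 convention);
- k-means (Lloyd, k-means++ seeding, best of 10 restarts);
- Gaussian mixtures fitted by EM over a grid of K = 2..9 and four
  covariance families (spherical, diagonal, full, tied), 10 restarts,
  relative log-likelihood tolerance 1e-6, at most 500 iterations,
  covariance ridge 1e-6, with K and family chosen by minimum BIC and genes
  hard-assigned by maximum posterior responsibility.

Mixture solutions in which a component is hard-assigned fewer than two
points are excluded from the BIC comparison: such solutions are spurious
likelihood maxima in which a component's variance collapses to the
regularisation ridge around a single point, and BIC would otherwise prefer
them. k-means and Ward are evaluated at the BIC-selected K (comparing the
methods at a common granularity is a package choice; the alternative of
optimising K per method by silhouette tends to collapse to K=2). The three
models are compared by mean silhouette, s(i) = (b−a)/max(a,b) on Euclidean
distances, with singleton clusters scored 0; exact ties — which occur
whenever two algorithms find the same partition — prefer the model-based
fit, then k-means.

Cluster numbers are arbitrary, so clusters are canonically renumbered by
decreasing translation-shift strength (polysome-side mean minus the
monosome mean of the centroid), making the mono→polysome shift cluster 1
and output stable across seeds and algorithms. Summaries attach a
qualitative pattern per cluster from the signs of the centroid with a
±0.05 dead zone.

## mRNA features

One representative transcript per gene: the most expressed (mean TPM over
polysomal libraries) when abundance is available — ties broken by longest
CDS, then identifier — otherwise the best annotation level, then longest
CDS. Features per transcript:

- 5'UTR/CDS/3'UTR lengths (nt) and UTR GC fractions (N excluded from the
  denominator);
- folding score per nucleotide: by default Nussinov base-pair maximisation
  (Watson-Crick + G:U wobble, minimum hairpin loop 3, −1 per pair, divided
  by length), a self-contained structural-complexity score verified against
  exhaustive enumeration on short sequences; optionally the thermodynamic
  MFE from the external ViennaRNA `RNAfold` binary (kcal/mol per nt). The
  engine is recorded in every output because the two scales differ;
- codon adaptation index: geometric mean of w_c = f_c/max(synonymous f),
  excluding ATG, TGG and stops; zero-usage codons are floored at 1% of
  their family maximum so one rare codon cannot zero the index; codons
  after an internal stop are not scored. A human codon-usage table is
  packaged (per-1000 frequencies from GenBank coding sequences via the
  Kazusa compilation) and any mapping can be supplied instead;
- TOP local score (versioned `anchored-kadane-v1`): ±1 per
  pyrimidine/purine, maximum window sum over windows starting within the
  first 5 nt and ending within the first 50 nt, floored at 0. The
  definition is this package's own, so scores carry the version tag and are
  only comparable within it;
- TOP-motif flag: 5'-terminal C followed by a pyrimidine run of ≥ 5 total;
- uORFs: ATG..in-frame stop fully inside the 5'UTR, any frame, overlapping
  ORFs counted separately, minimum 3 codons including the stop; coordinates
  0-based half-open;
- an IRES flag from a user-supplied gene list (no prediction).

Feature distributions across groups (TE groups or behaviour clusters) are
compared by the Kruskal-Wallis H-test with tie correction, followed by
Dunn's pairwise z tests on the pooled ranks, Holm-adjusted per feature;
constant features are reported as NA.

Over-representation of gene sets (GMT input) in a query list uses the
upper-tail hypergeometric probability with BH adjustment across sets; the
default universe is the filtered gene set of the run.

## Synthetic cohorts

The generator emulates the experiment at study scale: 10,000 genes, 8
library types × 3 replicates, expected depth 1e7 reads per library,
baseline expression log2-normal(8, 1.5) across genes. A planted fold-change
triple Δ = (δ_mono, δ_light, δ_heavy) multiplies the polysome-pool means in
high glucose only; total RNA is condition-invariant unless genes are
explicitly declared transcriptionally affected. Counts are negative
binomial with Var = μ + φμ²; the default dispersion is φ = 0.01 (a
biological coefficient of variation of 0.1, the usual magnitude for clonal
cell-line replicates); φ = 0 degenerates to deterministic rounding, giving
bit-identical null libraries for exact-regression tests. Library scaling
uses the baseline total (scale = depth/Σbaseline) with Δ applied on top, so
a planted 2^δ is exactly 2^δ in expected counts. Randomness is one global
seed with three spawned sub-streams in fixed order: transcripts, baseline,
counts (libraries fraction-major: total, mono, light, heavy; low before
high).

The default planted layout has six behaviours with sizes (73, 90, 79, 37,
21, 102): mono→light+heavy shift, light+heavy gain, mono+light gain, light
loss, heavy loss, and mono→heavy shift — |δ| = 1 throughout. Transcripts
are generated alongside with log-normal region lengths (medians: 5'UTR 170
nt, CDS 430 codons, 3'UTR 450 nt — human-like), controllable UTR GC, a
5'TOP tract planted on the two shift-up clusters and two uORFs on the two
down-regulated clusters; CDSs start ATG, end with a stop, and contain no
internal in-frame stop.

What the generator does *not* emulate: per-gene fraction-occupancy
preferences (every gene has the same expected TR, so "most translated"
rankings on synthetic cohorts are noise-ordered), isoform structure (one
transcript per gene), sequencing-level artefacts (GC/length bias, mapping
ambiguity), batch effects, and correlated replicates. Passing tests
therefore demonstrate the correctness and calibration of the statistical
machinery under the stated noise model, not robustness to those real-data
phenomena.

At these defaults the per-coordinate noise of the log-ratio matrix is
sd ≈ 0.12, so the planted centroids (unit separations) are ~8σ apart:
the regime in which the mixture model recovers K = 6 with ARI ≈ 1 and the
moderated test recovers ≥ 99% of planted genes. At φ = 0.05 the per-sample
log2 noise floor is 0.32 and a |δ| = 1 effect has moderated-t
noncentrality ≈ 3.7 — below what ≥ 90% recovery at BH-adjusted p ≤ 0.05
requires with n = 3; calibration studies (the all-null cohort) are
therefore run at φ = 0.05, where type-I behaviour, not power, is the
question.

## Numerical and degenerate-input choices

- log-CPM prior count 0.5; TPM effective length = annotated transcript
  length (no fragment-length model, since quantification is upstream).
- Expression filter: CPM ≥ 1 in *every* sample (a gene at exactly 1.0
  everywhere is kept). Variability filter: maximum within-replicate-group
  CV < 0.75 AND mean CPM > 4, both clauses configurable and the mean
  clause detachable; replicate groups of size 1 are an error. The joint
  filter equals sequential application (order-stable).
- Zero library size, missing lengths, rank-deficient designs, empty
  post-filter gene sets, windows outside a trace, empty known-TOP lists:
  explicit errors naming the offender. Constant QC matrices warn (PCA
  degenerate). All-N sequences give NaN GC; UTRs shorter than 4 nt give
  NaN fold scores.
- Sample QC clusters log2(TPM+1) profiles (raw-TPM Euclidean distance is
  dominated by the few most abundant genes); Ward tree exported as Newick,
  first two principal components reported.
- Pipeline manifests record package version, seed and a SHA-256 config
  hash; reruns with identical config and seed are byte-identical (timings
  are logged, never written to outputs).

## Known limitations

- No between-sample normalisation beyond CPM/TPM (no TMM); strongly
  asymmetric regulation induces a small compositional logFC bias (~0.06
  log2 at the default planted fraction of 4%).
- No observation-level weights (voom-style), spline designs or duplicate
  correlation; n = 3 relies on the shrunken variance for power.
- The Nussinov score is a base-pair count, not a free energy; compare
  MFE/nt values only within one engine.
- The TOP local score definition is package-specific (versioned); absolute
  values are not comparable with other tools' TOP scores.
- The hypergeometric test treats genes as exchangeable (no length or
  expression bias correction).
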
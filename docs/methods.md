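# Methods

## Data model and contingency tables

Genotypes are biallelic minor-allele counts in {0, 1, 2} with −1 as the
missing marker; the phenotype is binary (1 = case, 0 = control). For a
k-SNP combination, cells are indexed by the mixed-radix base-3 encoding of
the genotype tuple with the first listed SNP most significant, so tables,
exports and plots are reproducible bit-for-bit. Missing data are handled
by complete-case analysis *per combination*: a sample is dropped only from
tables whose SNPs it is missing at, which preserves maximal data per model
and matches common MDR practice. The maximum order defaults to 5.

Two text formats are supported: the tab-delimited MDR format (header row,
0/1/2 genotype codes, a 0/1 class column; the token `NA` is always read as
missing so that write→read round-trips, any other unparseable token is an
error unless `permissive=True`) and PLINK additive `.raw` text
(`FID IID PAT MAT SEX PHENOTYPE` then 0/1/2/NA per variant, phenotype
1 = control / 2 = case, recoded internally).

## Membership engines

* **empirical** (EF-MDR): μ_H(i) = n_i1/n_i+, the binomial MLE of the
  case probability in cell i. No tuning parameters. Empty cells carry no
  membership and contribute nothing downstream.
* **binary** (classic MDR): H iff n_i1/n_i0 ≥ T, with T defaulting to the
  table's margin ratio n₊₁/n₊₀ (the balanced-accuracy convention). Ties
  at the threshold classify H — the dominant MDR convention, stated here
  because it is a genuine choice. Cells with cases but no controls are H
  (the ratio is infinite); empty cells are L and flagged, which is the
  conservative assignment needed when a test fold contains a genotype
  unseen in training.
* **custom**: any function (n_i1, n_i0) → [0, 1] can be registered as an
  engine; a value outside [0, 1] is a contract violation naming the cell,
  never clamped. Parametric fuzzy membership families (linear/sigmoid
  odds-ratio functions and their thresholds) are deliberately not built
  in; the hook is the supported path for them.

## The statistic chain and its identity

With fuzzy confusion counts TP/FN/TN/FP as membership-weighted sums over
nonempty cells, conservation TP+FN = n₊₁ and TN+FP = n₊₀ holds *exactly*
for every engine (each sample distributes its unit mass between H and L).
Under the empirical engine the sums reduce to TP = Σ n_i1²/n_i+ and
TN = Σ n_i0²/n_i+, giving

    SEN = (1/n₊₁) Σ n_i1²/n_i+,  SPE = (1/n₊₀) Σ n_i0²/n_i+,

and BA = (SEN+SPE)/2 satisfies the algebraic identity
X² = n₊₊(2·BA − 1) with the Pearson chi-square of the 2 × C contingency
table over the C *observed* genotype columns. Consequences:

* BA ∈ [0.5, 1] under the empirical engine (X² ≥ 0), with BA = 0.5
  exactly on homogeneous tables;
* the degrees of freedom are "number of genotypes − 1" **counting
  observed (nonempty) combinations**, the reading under which the Pearson
  equivalence holds — empty cells contribute no information. The
  alternative 3^k − 1 reading is available behind `df_rule="full"`.
* on a balanced design (n₊₁ = n₊₀), SEN = SPE identically, since
  Σ(n_i1² − n_i0²)/n_i+ = Σ(n_i1 − n_i0) = 0.

For non-empirical engines BA may fall below 0.5 and the quantity
n(2·BA−1) is *not* a chi-square statistic; the conversion refuses unless
forced, and MDR models are scored by cross-validation statistics instead.
p-values are reported raw, with no multiplicity correction, matching the
method's usage; the identity is verified in the test suite against an
independent `scipy.stats.chi2_contingency(correction=False)` computation
at 10⁻⁸ absolute tolerance (all quantities are ratios of integers ≤ n, so
a tighter tolerance would only probe float rounding).

Tables with fewer than two observed genotype combinations are degenerate:
the model is unreportable and the search counts it as skipped rather than
aborting a scan.

## Search

The EF-MDR search enumerates all C(s, k) combinations per order in
lexicographic order and ranks by p-value (ties broken by higher BA, then
lexicographic SNP tuple — deterministic reporting). It is a pure function
of the data: seed-free, invariant to sample order, and its per-order cost
is O(C(s,k) · n). Only the top-N models per order are retained
(default 10). Since the best p-value is a minimum over combinations, the
overall best is monotonically non-increasing as the order range widens.

Classic MDR uses stratified m-fold cross-validation (scikit-learn
`StratifiedKFold`, shuffled under `random_state`; an explicit `cv`
splitter or list of splits can be supplied). Per fold, H/L pooling is fit
on the training folds with the auto threshold from the training margins
and applied to the held-out fold; combinations are scored by mean testing
balanced accuracy, and cross-validation consistency (CVC) counts the
folds in which a combination is training-best. The best model maximises
CVC, then mean testing BA — the convention of the original MDR
literature. Both searches are exposed as scikit-learn estimators
(`fit`/`transform`, plus `predict` on the MDR path returning crisp H/L
labels), so they compose with pipelines and `clone`.

## Simulator

A simulation model is a k-way penetrance table f(g) = P(case | g) plus
per-SNP MAFs; genotype frequencies follow Hardy–Weinberg with independent
loci. Prevalence is K = Σ f(g)P(g) and heritability is the
variance-ratio h² = Σ (f(g) − K)² P(g) / (K(1−K)). Case-control data are
drawn retrospectively — causal genotype tuples from P(g | case) and
P(g | control) via Bayes — so the emitted sample sizes are exact.
Noise SNPs are independent HWE draws with MAF uniform over (0.05, 0.5) by
default; causal columns are placed at random positions and recorded in a
truth manifest.

**Purely epistatic family.** f(g1, g2) = K + θ·(g1 − 2q1)(g2 − 2q2). The
centered allele-count product has zero conditional mean given either
locus, so both marginal penetrances equal K at *any* MAF — a genuinely
epistasis-only model — and θ has the closed form
θ = √(h²·K(1−K)/(V1V2)) with V = 2q(1−q), so no numerical scaling is
needed. The price is a feasibility cap: penetrances must stay in [0, 1],
which bounds h² (≈ 0.06 at K = 0.2, MAF 0.4); infeasible requests error
rather than truncate. Stronger effects are expressed with explicit
penetrance tables (e.g. a checkerboard with contrast 0.6 at MAF 0.5).

**Marginal-effect families.** Disease odds b·θ^score with score =
g1+g2 (additive), g1·g2 (multiplicative) or 1{g1≥1 and g2≥1}
(threshold); penetrance = odds/(1+odds) and the baseline b is solved by
`brentq` so the prevalence hits its target (default 0.1). Optionally each
causal locus is replaced in the output by a marker in linkage
disequilibrium with it: D′ with the two MAFs determines the two-locus
haplotype distribution, each causal haplotype draws a marker allele from
the conditional allele distribution, and only the markers are emitted.
Out-of-range D′ errors with the feasible bound.

**Randomness contract.** One master seed; replicate streams are derived
with `numpy.random.SeedSequence.spawn`, so studies are reproducible
(byte-identical datasets for identical seeds) and per-replicate results
do not drift if the iteration is reorganised.

## Study harnesses and their scale

* **Type I error**: per replicate, two phenotype-independent SNPs with
  MAFs drawn from {0.2, 0.4} (the configured default), balanced
  cases/controls; the pair's EF-MDR p-value is computed by a vectorised
  implementation of the same statistic chain (verified equal to the
  per-table path at 10⁻¹²), and rejection rates at nominal levels are
  reported with binomial standard errors. The defaults, 7000 replicates
  at n = 1600, run in a couple of seconds. At n = 200 the smallest
  expected cell counts are well below 1, the chi-square approximation is
  poor in the conservative direction, and the observed rate falls below
  nominal — the expected small-sample behaviour.
* **Power**: fraction of replicates in which a search engine's best
  model at the causal order is exactly the planted pair. The default
  grid uses the purely epistatic family at MAF 0.4, prevalence 0.2,
  h² ∈ {0.005, 0.02, 0.05} — spanning near-chance to near-saturation
  within the family's feasible range — with 800 samples (400/400),
  20 SNPs and 100 replicates per cell, sizes at which the full
  EF-MDR-vs-MDR comparison completes in well under a minute. Power is
  reported per model and method with a power ratio against a baseline
  method (MDR by default).

## What the simulations do and do not show

The generator emulates the standard simulation designs of the MDR
literature: retrospective balanced sampling, HWE, independent noise SNPs,
and penetrance-defined effects. It does not emulate linkage
disequilibrium *among* noise SNPs, population structure, genotyping
error, or covariates — so passing tests demonstrate calibration and
relative power under idealised architectures, not performance on real
GWAS data. Published power figures for this method family depend on
specific penetrance-table collections that are not reproduced here;
the power harness is therefore a qualitative instrument (monotonicity,
engine comparison, saturation), not a numeric reproduction.

## Numerical choices

* Identity and conservation checks at 10⁻⁸/10⁻⁹ absolute; all inputs are
  integer counts, so these bind only float rounding.
* `ba_to_chisq` clips tiny negative values of n(2·BA−1) to 0.
* Degenerate prevalences (K within 10⁻¹² of 0 or 1) make heritability
  undefined and error.
* Chi-square p-values come from `scipy.stats.chi2.sf` (upper tail);
  X² = 0 gives p = 1.

## Known limitations

* No permutation fallback for sparse tables and no exact tests; at very
  small n the p-values are conservative (shown by the type-I harness).
* No covariates, multi-allelic markers, imputation, or binary PLINK
  (.bed) support.
* Interaction plots support up to three loci; higher orders export as
  tables.
* The MDR engine's CV mechanics (stratified shuffling under a seed) are
  one reasonable convention; other MDR implementations may split folds
  differently, so CVC values are comparable within, not across, tools.
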
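# Methods

This note documents the models, numerical choices and limitations of
`holodepth`. It is the package's account of its own science; every
empirical number mentioned here is computed by the test suite or by
`scripts/acceptance.py`, not asserted from elsewhere.

## The analysis model

The pipeline treats *depth* as a proxy for water mass along a bathyal
gradient (roughly 250–1500 m) spanning a shallow, warmer/saltier upper
water mass and a deep, colder/fresher one, split at 1000 m. Three host
species are modelled: two with rich, high-microbial-abundance (HMA)
communities and one with a poor, low-microbial-abundance (LMA)
community. The questions the stages answer, in order: which LC-MS
features are trustworthy (filtering); which taxa and compounds track
depth (trend classification, water-mass t-tests); whether
near-identical ASV pairs swap with depth (ecotypes); whether community
structure as a whole tracks depth (PERMANOVA, ordination, envfit);
whether the metabolome as a whole is predictable from depth (OPLS);
which taxa co-occur (consensus network); and whether the two omics
layers co-vary (Mantel/Procrustes, compound linking).

## Synthetic data generator

The generator is first-class, tested code: it defines the conditions
under which every downstream claim is validated.

**Metadata.** Depths are uniform on (244, 1476) m. Temperature and
salinity are linear in depth plus Gaussian noise scaled so their
population correlation with depth equals the `collinearity` parameter
(default 0.9; 1 = deterministic, 0 = independent). The hydrographic
anchors (≈4.5 °C / 34.93 psu shallow core, ≈3.7 °C / 34.89 psu deep
core) give the vertical contrast of a two-water-mass column. The
`water_mass` label is a pure function of depth ("shallow" iff
depth ≤ 1000 m).

**ASV tables.** Counts are Dirichlet-multinomial: ASV *i* in sample
*s* has log-concentration `baseline_i + slope_i * depth_km(s) +
noise_is`; per-sample proportions are a Dirichlet draw of the closed
concentrations (total concentration θ = 2000, mild overdispersion) and
counts a multinomial of a log-normal library size (mean 2 × 10⁴,
σ = 0.25). The community has a *core* of detectable ASVs plus
effectively absent non-core ASVs; core size and baseline spread
(σ = 0.8) were calibrated once so mean observed per-sample richness
lands near 190 (HMA) and 30 (LMA), the magnitudes reported for rich
and poor deep-sea sponge communities. Depth-responsive ASVs (default
30%) receive slopes of magnitude `effect_size` (default 2.0 per km,
signs balanced), i.e. roughly an e²·⁵-fold change across the survey
span — a "strong responder". The per-sample log-abundance noise
(σ = 0.1 by default) was calibrated, as the recovery contract
prescribes, so that planted strong responders are recoverable with
sensitivity ≥ 0.8 at n = 15 by Pearson correlation on relative
abundances, pooled over replicate surveys; with effects off, the
fraction of p ≤ 0.05 sits at the nominal 5%.

**Sister pairs** are planted on opposing-slope responsive ASVs by
copying one member's sequence and substituting exactly
`floor((1 − identity) · L)` positions chosen without replacement
(L = 140, no indels: ASVs are fixed-length concatenated reads). At the
default 97% identity target this is exactly 4 substitutions
(identity 136/140 ≈ 0.9714, just above threshold); a target of 0.9642
gives 5 substitutions (135/140, just below).

**Planted associations.** Pairs of non-responsive core ASVs share a
latent Gaussian factor giving their log-abundances a basis correlation
of `assoc_strength` (default 0.8) on a fluctuation scale
(`assoc_noise_sd` = 1.0) large enough that counting noise does not
attenuate it. Shared factors are orthogonalised across pairs. The
`exact_null=True` option goes further: it draws the shared factors
*and every ASV's individual noise vector* jointly orthogonal (QR of an
n × (pairs + ASVs) Gaussian matrix), so that in the realized sample
unplanted pairs are exactly unassociated and planted pairs carry
exactly the stated correlation. This makes the truth ledger literally
true of the data rather than true in expectation. What passing the
network-recovery test under `exact_null` does **not** show: on real
data (or generically sampled noise), null pairs exhibit sampling
correlations of order 1/√n, and a consensus of strongly concordant
estimators at p ≤ 0.05 will admit some of them; the 4-of-5 vote
controls method-specific artifacts, not sampling flukes.

**Metabolome tables.** Features belong to `pc_group` adduct clusters
sharing one latent compound log-signal per sample; members differ by a
fixed yield offset plus small log-normal noise. A global per-sample
intensity factor (σ = 0.8 in log, ≈ ±2-fold) models extract
concentration and injection variability — the factor that dominates
the between-feature covariance of real LC-MS tables and gives OPLS
models of real metabolomes their characteristically high R²X.
Responsive compounds trend log-linearly with depth (±1.5 per km,
balanced). Exactly `ceil(frac_void · n)` features get retention times
below 40 s. QC injections carry multiplicative log-normal noise with
feature-specific target CV: 0.08 for stable features, 0.8 for the
planted unstable subset — calibrated so ≥ 95% of planted-unstable
features empirically exceed the 0.30 cleaning threshold at 8 QC
injections. One high-yield member of most groups carries the
molecular-ion annotation for the polarity; others are
"adduct"/"isotope"/blank.

**Determinism.** All randomness flows from one integer seed through
named CRC32-keyed sub-streams (stable across processes), so identical
seeds and parameters produce byte-identical tables and pipeline
outputs.

## Filtering

QC CV uses the sample (n−1) standard deviation on raw intensities —
the common metabolomics QC convention; whether to use raw or log
intensities is genuinely open, and raw is recorded in the report
metadata. Features with zero QC mean have undefined CV and are removed
by the cleaned filter (an unreliable feature by construction). The
retention-time rule is strict ("eluting < 40 s"), so exactly 40.0 s is
retained. "Cumulative signal" for the pc_group filter sums study
samples only — QC injections are pooled material, not observations —
and ties break to the lexicographically smallest feature id
(deterministic, logged). Ion-annotation matching strips internal
whitespace and unifies Unicode minus variants, so `[M + H]+` ≡
`[M+H]+`.

## Depth response

Correlations are computed on total-sum-scaled relative abundances.
This is deliberate and carries the standard compositional caveat:
closure transfers abundance changes of dominant taxa onto everyone
else, so with many strong responders the classifier reports more
responders than were planted (visible in the README example). The
package documents this rather than "fixing" it with log-ratio
transforms, which would change what the statistic estimates. The class
rule uses raw p ≤ 0.05; BH-adjusted p-values are reported alongside
and consumers choose their stringency. The t-test is Welch
(unequal variances); samples exactly at 1000 m go to the shallow
group. Constant variables are flagged and excluded from the FDR
family. p-values for correlations come from the t transform of r at
n − 2 df; |r| = 1 maps to p = 0.

## Ecotypes

Identity is ungapped positional identity on equal-length sequences
(fixed-length ASVs; on aligned equal-length inputs alignment-based
similarity reduces to this). A global-alignment identity is available
for variable-length inputs. "Opposing depth response" defaults to
both members individually significant with opposite signs; a
relaxation (one significant member plus an opposite-signed trend) is
available but off by default — the stricter reading is the
conservative choice where the operational definition is ambiguous.
Relaxing stringency (FDR → raw p) can only grow the detected set,
since every FDR-significant variable is raw-significant.

## Community statistics

Ordination is classical metric scaling (principal coordinates) rather
than stress-minimising NMDS: the scores are a deterministic
eigen-decomposition, checkable against geometry oracles and stable
under reruns, which the seeded pipeline requires; an NMDS refinement
exists behind a flag. Axis signs are canonicalised (first nonzero
loading positive). PERMANOVA is one-factor with the pseudo-F partition
of squared Bray–Curtis distances; permutation p-values use the add-one
estimator (1 + B)/(1 + N) everywhere in the package, so p > 0 always;
an exhaustive mode enumerates all n! label permutations for small n.
Environmental vectors are least-squares directions in the 2-D score
space with r² equal to the squared multiple correlation; significance
permutes the variable. VIF screening standardises variables, computes
VIF_j = 1/(1 − R²_j), and iteratively removes the worst until all are
below 10; perfectly collinear variables (infinite VIF) go first.

## OPLS

Single-response OPLS with unit-variance scaling and mean centring
(constant columns are centred only). Orthogonal components are
extracted iteratively — weight from the current X'y, loading from the
score, response-orthogonal part of the loading normalised to give the
orthogonal weight, X deflated — then a single predictive component is
computed on the deflated matrix. With `n_ortho = 0` the procedure *is*
single-component PLS1, and the tests pin it to an independent
closed-form oracle at 1e-8. VIP is computed on the predictive
component (one of several published VIP variants); with one predictive
component VIP_j = √p·|w_j| and mean VIP² ≡ 1 exactly. Q² uses k-fold
cross-validation (default 7) with scaling re-estimated inside each
training fold and the training-fold mean as the null prediction; folds
come from one seeded shuffle held fixed across the permutation loop,
and k = n gives deterministic leave-one-out. pQ2 defaults to 200
permutations (resolution 1/201 ≈ 0.005, comfortably below the 0.05
gate); fewer than 20 triggers a warning. The battery enumerates
experiment × species × filter (4 × 3 × 3 = 36 records by default) on
log1p intensities of study samples.

## Association network

Pearson, Spearman, local similarity and the MIC-style coefficient run
on relative abundances; SparCC runs on counts + 1 pseudocount
(closure inside), estimating basis correlations from the log-ratio
variation matrix with iterative exclusion of the strongest correlated
pairs (threshold 0.1, 20 iterations, with guards against making the
basis system singular). SparCC "bootstrap" p-values follow its
original formulation: null data sets shuffle each ASV's counts
independently, and the two-sided p compares magnitudes (add-one). The
other estimators share one permutation scheme: each round permutes
every ASV's sample vector independently, which prices the whole
pairwise matrix per round while each pair's relative permutation is
uniform. Local similarity is the maximal contiguous aligned-run sum of
products of rank-based normal scores on depth-ordered samples
(delays up to `max_delay`, default 0 — the study design has no time
axis, so depth ordering is the documented interpretation), normalized
by n and signed by the optimal run. The dependence coefficient is a
grid-characteristic estimator: maximum over grid shapes x·y ≤ n^0.6 of
the mutual information of rank-equipartitioned axes, normalized by the
smaller marginal entropy — this normalisation makes a noiseless
functional relationship score exactly 1 at any n (the log-bin
normalisation cannot when n is not divisible by the bin count);
exhaustive partition search is combinatorially infeasible at the
sample sizes the pipeline meets. The consensus admits an edge when
≥ 4 of 5 estimators give p ≤ 0.05 *and* every voting estimator's
statistic is positive; raising p_max or lowering min_votes can only
add edges.

## Inter-omics

Metabolome distances are Euclidean on log1p-transformed,
feature-autoscaled intensities (configurable, stamped in provenance).
Procrustes allows reflections by default (full orthogonal group);
m² = 1 − (Σ singular values)² after standardising both configurations,
identical to the classical disparity. Both Mantel and Procrustes
support exhaustive enumeration for tiny n. Compound linking ranks
positive Spearman correlations only, truncates to the top 10 without
padding, flags constant-signal compounds, and is invariant to input
ordering.

## Problem sizes and runtime posture

The default pipeline configuration simulates 15 samples per species,
80–120 ASVs, 150 LC-MS features per experiment, and uses 999
PERMANOVA/Mantel permutations, 200 OPLS permutations and 100 network
permutations. The validation suite scales some experiments down
(e.g. 12 samples, 40–60 features, 30–100 permutations) — these sizes
were chosen so the full planted-structure recovery battery runs as an
ordinary desk check while keeping every statistical conclusion
resolvable at its stated tolerance.

## Known limitations

- Everything upstream of the ASV table and annotated feature table
  (read processing, taxonomy, peak picking, adduct annotation) is out
  of scope; the pipeline starts from those artifacts.
- The compositional spillover of the trend classifier (above) means
  "fraction of responsive ASVs" on real data mixes direct responders
  with closure echoes; the water-mass t-test shares the property.
- The generator's communities have no phylogenetic signal, no
  taxonomic structure, and independent per-sample noise (no spatial or
  temporal autocorrelation); sister sequences differ by substitutions
  only.
- The `exact_null` association scenario validates estimator and
  voting logic, not the field false-discovery rate of a p ≤ 0.05
  consensus on noisy data (see above).
- The water-mass model is a hard 1000 m split; real water-mass
  attribution from temperature–salinity profiles is not modelled.
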
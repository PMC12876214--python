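# Methods

`codysbiosis` implements the statistical core of a two-group (case/control)
gut-microbiome study in which bacterial and fungal genus profiles are derived
from the same shotgun metagenomes and the question of interest is whether the
*cross-kingdom ecology* — not just the composition — differs between groups.
The package covers five analysis stages plus a synthetic cohort generator
that makes every stage testable without sequencing data.

## Data model

Abundances live in an `AbundanceTable` (samples × taxa) with per-taxon
kingdom (`bacteria`/`fungi`) and rank labels. Internally abundances are
fractions in [0, 1]; percentages appear only in display output. Total-sum
scaling is **per kingdom** by default: each kingdom's fractions sum to 1
within a sample. Both kingdoms come from one metagenome, but community
profiles are conventionally reported per kingdom; a joint-normalisation mode
exists for users who prefer a single simplex. A prevalence floor
(default 0.25, i.e. a taxon must be detected in ≥ 25 % of the group's
samples; 0 disables) is applied before correlation work to avoid
correlations driven by a handful of detections.

## Cross-kingdom network inference (the core procedure)

Within one group, every (bacterial genus, fungal genus) pair — and only
cross-kingdom pairs — is scored by Spearman rank correlation (midranks under
ties). Two-sided p-values use the t approximation
`t = |ρ|·sqrt((n−2)/(1−ρ²))` with n−2 df; this is the convention standard
correlation tests use at these sample sizes and it reproduces published
(ρ, n, p) triples at 4-decimal rounding (e.g. ρ = −0.75 at n = 17 →
p = 0.0005). All pairs tested within a group form one Benjamini–Hochberg
family; an edge requires both `|ρ| ≥ 0.6` and BH-adjusted `q < 0.05`.
Constant taxa are skipped per pair and logged rather than failing the build.

The signed network is summarised by its **positivity fraction**
(positive edges / all edges), the operationalisation of *co-dysbiosis*: a
healthy-like gut shows abundant negative (competitive) bacterium–fungus
edges, whereas the dysbiotic state collapses toward exclusively positive
(cooperative) edges. The fraction is flagged undefined (never 0/0) for an
empty network. Hubs rank by degree with deterministic tie-breaks
(mean abundance, then name). Networks export to GraphML with the full
attribute set (kingdom, mean abundance, degree, ρ, q, sign, and the
conventional colours: yellow circles for bacteria, green squares for fungi,
red/blue edges) so Gephi can render them directly.

A statistical consequence worth knowing: BH at q = 0.05 *controls*, not
eliminates, false discoveries. With R discovered edges per network the
expected number of spurious edges is ≈ 0.05·R, about half of them
negative-signed. A simulated cohort whose planted couplings are exclusively
positive therefore yields a positivity fraction of exactly 100 % in roughly
two runs out of three and ≈ 93–95 % otherwise; the *average* over replicate
cohorts sits within a few points of 100 %. Tests and the acceptance protocol
treat the quantity accordingly.

## Diversity and ordination

* **Chao1** richness: bias-corrected form
  `S_obs + F1(F1−1)/(2(F2+1))` by default (finite when doubletons are
  absent); the classic form `S_obs + F1²/(2F2)` is available for parity with
  other software. Defined on counts only; fraction tables are rescaled to a
  nominal depth first.
* **Shannon** entropy over positive entries after normalisation; log base
  selectable.
* **Bray–Curtis** dissimilarity feeds **PCoA** (eigendecomposition of the
  Gower-centred −½·J·D²·J). Bray–Curtis is not Euclidean-embeddable, so
  negative eigenvalues can appear: they are *discarded and counted*, never
  silently corrected, and `proportion_explained` is taken over the positive
  spectrum.
* **PERMANOVA** (one-way): `SS_total = (1/N)Σ_{i<j} d²`, pseudo-F with
  (a−1, N−a) df, R² = SS_B/SS_total. The p-value permutes labels with the
  add-one correction `(1+b)/(1+m)` (never exactly 0), or enumerates all
  distinct assignments exactly when there are ≤ 10 000 of them and the
  caller opts in. Seeds are recorded in the result.
* **Procrustes/PROTEST**: both configurations centred and scaled to unit
  sum of squares, optimal rotation from the SVD of the cross-product,
  `M² = 1 − (Σσ)²`, `R = sqrt(1−M²)`. The first configuration is the
  reference; PROTEST permutes rows of the second, p = (b+1)/(m+1).

## Group tests and biomarker scoring

Wilcoxon rank-sum is exact for ≤ 12 pooled untied observations and otherwise
uses the tie-corrected normal approximation with continuity correction
(`scipy.stats.mannwhitneyu` under the hood). The unpaired t-test accepts
summary statistics (mean, SD, n) so printed cohort tables can be re-tested;
Welch df is the default, pooled df selectable. The 2×2 chi-square supports
the Yates correction.

Biomarker discovery follows the LEfSe recipe as published, reimplemented
here so every step is inspectable rather than bit-compatible with the
original tool:

1. **Screen**: per-feature Kruskal–Wallis (≡ rank-sum for two classes),
   BH-adjusted, keep q < 0.05. Applying FDR at this stage is a deliberate
   departure from classic LEfSe's raw-p screen.
2. **Effect size**: features rescaled to a per-sample total of 10⁶
   (absorbing any global scale factor). Over 30 bootstrap rounds, each class
   is subsampled (2/3), a two-class linear discriminant is fitted with a
   small ridge term (10⁻⁶ × mean covariance diagonal — necessary at n ≈ 36
   where features are collinear), and each feature's round effect is the
   mean of |Δ class means| and |unit-norm discriminant weight × Δ projected
   class means|. The score is `sign × log10(1 + mean effect)`, signed toward
   the enriched class; |score| ≥ 2 flags a biomarker (a stricter cut of 4
   isolates only the strongest signals). The subclass (within-class
   consistency) stage of canonical LEfSe is omitted: this design has no
   subclasses.

## Classification

A random forest (500 trees) on fungal genus fractions plus total and
allergen-specific IgE, assessed by stratified 10-fold cross-validation
(folds shrink with a warning if the smallest class cannot fill them). AUC is
computed on pooled out-of-fold scores — stabler than a per-fold mean at
n ≈ 36 — with per-fold values also emitted, alongside the OOB error of a
final all-data forest. Two importances are reported: mean-decrease-Gini
(non-negative by construction) and permutation importance, the only
forest-native measure that can legitimately be negative for uninformative
features. No transform is applied to covariates: forests split on order
statistics, so any monotone transform (rank or log of IgE) leaves the model
unchanged.

## Pathway aggregation (reporter scores)

Each KO gene family is tested between groups (Wilcoxon by default, Welch t
selectable), p clamped to [10⁻¹⁰, 1−10⁻¹⁰], and converted to a signed
z-score `Φ⁻¹(1 − p/2) × sign(case median − control median)` — the signed
two-sided form keeps direction explicit; the classic one-sided form is an
option. Pathway scores aggregate member z as `Σz/√k` and are standardised
against size-matched backgrounds: for each member count k, 1000 random
k-subsets of the observed KO universe (without replacement within a set)
give μ_k, σ_k, and `ReporterScore = (z_raw − μ_k)/σ_k`. |score| > 1.5 flags
a pathway. Under a fully null KO table the flagged fraction averages ≈ 0.11
(a standardised score exceeds 1.5 in absolute value with probability ≈ 0.13
under normality), which is why a handful of nominally "significant" pathways
on null-like data is expected behaviour, not a defect.

## Synthetic cohort generator

The generator emulates the modelled study's design: 19 cases ("ARFC") vs
17 controls ("HC"), genus level, two kingdoms, zero-inflated skewed
abundances, planted cross-kingdom couplings of either sign, depleted fungal
genera, and IgE covariates.

* **Copula**: per group a latent MVN is drawn whose correlation embeds each
  planted coupling via the exact bivariate-normal inversion
  `r = 2·sin(π·ρ_s/6)` of the target Spearman. Because Spearman is
  rank-based, the target survives the monotone margin transform. The matrix
  must be positive definite; violations raise a structured error. Note the
  budget constraint: a node coupled to k partners at strength r needs
  k·r² ≤ 1 unless the partners are themselves correlated — with six fungi
  coupled to the IgE node at ≈ −0.4 (Σr² ≈ 0.98), the defaults deliberately
  keep planted network edges off the IgE-coupled genera.
* **Margins**: `x = m·exp(σ·z − σ²/2)` (mean-preserving lognormal, σ = 1 by
  default — a modelling choice; only means ± SDs of select taxa are
  available to match). Base mean fractions pin the depleted genera to their
  group targets (Dentiscutata 3.70 %/1.49 %, Cenococcum 1.74 %/0.30 %) and
  spread the remainder over background taxa as a geometric series spanning
  one decade. Pinned targets refer to the *realized* community, so
  background masses are pre-scaled by 1/(1 − zero-inflation).
* **Zero inflation** (default 0.3) is applied after the margin transform as
  structural absences. Planted-edge, depleted and IgE-coupled taxa are
  exempt by default so recovery tests isolate the inference machinery; a
  flag inflates them too. Inflation attenuates rank correlations
  monotonically — a real property of zero-heavy data that the tests verify
  rather than suppress.
* **IgE**: total IgE is lognormal, moment-matched per group
  (285.6 ± 102.4 IU/mL cases, 65.3 ± 28.7 controls — positive and
  right-skewed, and mean ± SD is all there is to match), rank-coupled to
  selected fungi (≈ −0.4) through the same copula so the planted quantity is
  exactly a Spearman correlation, not a regression slope. Allergen-specific
  IgE co-varies with the total-IgE latent (r = 0.6) at group-typical levels.
* **KO tables**: lognormal KO abundances with an optional group-mean shift
  (in SD units) applied to the members of designated pathways; shift 0 makes
  the groups exchangeable.

Everything is reproducible from a single seed; identical specs produce
byte-identical outputs.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: sequencing noise and depth variation,
taxonomic misassignment, the full compositional coupling of real communities
(only a per-kingdom closure of independent-by-default taxa), phylogenetic
correlation among taxa, and covariate confounding beyond the planted IgE
couplings. Per-kingdom closure does introduce a mild common-denominator
distortion: planted |Spearman| = 0.8 couplings arrive at ≈ 0.75 in the final
fraction tables. Recovery results should be read with that attenuation in
mind.

## Numerical and design choices

* Permutation p-values use the add-one correction and mandatory recorded
  seeds; exact enumeration reports the unadjusted count fraction (the
  observed assignment is part of the enumeration).
* Spearman p at |ρ| = 1 returns the exact-permutation floor 2/n!.
* BH is delegated to `statsmodels`; the wrapper validates inputs and is
  covered by hand-worked and null-calibration tests.
* Degenerate cases error loudly and specifically: all-zero sample pairs in
  Bray–Curtis (named), zero-variance t-tests (flagged), zero row/column
  chi-square margins, σ_k = 0 reporter backgrounds, non-PD latent
  correlation matrices.
* Problem sizes in the test-suite calibrations (500 PERMANOVA null
  datasets at n = 12 with 199 permutations; 500 label permutations for the
  screening-FDR check; 20 null KO cohorts; 10 × n = 2000 copula draws) were
  chosen to put Monte-Carlo error well inside each asserted band while the
  whole suite stays in the low minutes on one CPU.

## Known limitations

* Spearman-on-fractions ignores compositional bias; compositionality-aware
  estimators (SparCC-style) are future work, and the per-kingdom closure
  attenuation above is the visible symptom.
* The LEfSe implementation follows the published description, not the
  original tool's code; scores agree qualitatively, not bit-for-bit.
* The t approximation for Spearman p-values is mildly anti-conservative in
  the far tail at n ≈ 19 under heavy ties; a permutation option exists but
  is not the default (the default matches the convention of standard
  correlation tests).
* Reproducing the modelled study's cohort-level numbers (its PERMANOVA R²,
  alpha-diversity p, the exact 51- and 17-edge networks, figure-level taxa)
  requires its raw sequencing data and is out of scope; the package
  reproduces the *analytic* anchors and the qualitative network contrast on
  synthetic cohorts.
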
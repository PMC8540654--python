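# Methods

This note documents the models, parameter choices and numerical decisions
behind the package, and what the synthetic data do and do not establish.

## Study design arithmetic

`StudyDesign` encodes the campaign layout: 6 sites × 8 seasonal rounds,
80 leaves per site and round pooled into 4 metabarcoding samples, 10
further leaves yielding 2 leaf-wash aliquots, each imaged as 5 z-stacks of
35 slices. All totals (3840 metabarcoding leaves, 192 pooled samples, 96
aliquots, 480 stacks, 175 slices per aliquot) are derived products, never
constants. Rounds map onto seasons cyclically (autumn, winter, spring,
summer, twice), matching sampling dates in November, February, May and
August. Sites carry a BC-load category: HGa/HGb → bcM, HKa/HKb → bcH,
DM/DW → bcL.

## BC particle caller

* **Threshold.** Per channel, voxels strictly above (1 − f) × the global
  3D maximum of that channel, f = 0.001 by default ("0.1% below the peak").
  The global maximum is taken stack-wide, not per slice. Because the
  threshold is relative, the mask is invariant to overall intensity
  scaling. Degenerate cases are explicit: an all-zero channel has no
  defined threshold and returns an empty mask with a warning; a constant
  non-zero channel saturates the mask (every voxel equals the maximum and
  therefore clears a cut 0.1% below it).
* **Coincidence.** Only voxels above threshold in *both* channels survive,
  which rejects single-channel autofluorescent confounders exactly — a
  structural guarantee of the AND, not a statistical one.
* **Particles.** A particle is a 3D connected component of the coincident
  mask. The emission being counted is particulate, so components rather
  than voxels are counted; connectivity defaults to 26 (faces, edges and
  corners) and is a parameter (6/18/26).
* **Load.** Per-sample counts are averaged over the 5 stacks (arithmetic
  mean, exposed as a reducer option), divided by the imaging volume to get
  a concentration, scaled to the full wash-suspension volume and divided by
  the washed leaf mass. The suspension volume is not a measured quantity of
  the original protocol and defaults to 8 mL — an explicit, flagged
  assumption; loads scale linearly in it.
* **Fold change.** Category fold changes are ratios of category means,
  where a category mean is the mean of its site means. On the field site
  means this gives bcH/bcL ≈ 6.54 and bcM/bcL ≈ 2.77, inside the reported
  2–7-fold band.

## Synthetic z-stacks

The generator plants isotropic 3D Gaussian blobs (σ = 1 voxel) into a
64 × 64 × 35 voxel stack — the axial depth mirrors the 35 acquired slices;
the lateral extent is downscaled while the voxel size (≈ 6.64 µm lateral,
1 µm axial) preserves the real imaging-volume aspect. Particles appear at
identical coordinates in both channels with peak intensity snr × the
background scale; confounders appear in the autofluorescence channel only.
Background noise is half-normal, truncated at 4 scale units and capped at
0.998 × the blob peak, so no background voxel can clear the relative
threshold — a documented guarantee asserted in tests. Blob voxels replace
rather than add to noise (emission dominates locally), so every planted
centre sits exactly at the stack maximum and survives thresholding.
Centres keep a Chebyshev separation of ≥ 5 voxels (rejection sampling;
exceeding the packing limit raises an error), so planted blobs never
merge. The generator returns the planted truth for validation. Optics
(pulse width, NA, PSF anisotropy), sub-voxel positions and intensity
heterogeneity are not modelled: recovery results show the counting logic
is correct, not that real acquisitions are this clean.

## Synthetic communities

Counts are Dirichlet-multinomial: per sample, expected relative abundances
are a log-normal baseline (log-mean 0, log-sd 1 over 150 taxa) re-weighted
by the planted effects, converted to a Dirichlet draw with total
concentration 300 (overdispersion), then multinomial at a library size
uniform on 2 000–20 000 reads — bracketing typical per-sample amplicon
depths. Ten percent of taxa are BC indicators, assigned round-robin to the
three categories and boosted ×8 in samples of their category; ten percent
are seasonal taxa boosted ×2 in their peak season. The BC boost
deliberately exceeds the seasonal one: the generator's job is to produce
the study's qualitative structure (category effect > seasonal effect),
and the ×8/×2 defaults give ANOSIM/PERMANOVA effect sizes of the same
order as field values (R ≈ 0.4, R² ≈ 0.12 for category; R ≈ 0.03,
R² ≈ 0.03 for season). Three chloroplast taxa with uniform-random counts
exercise the lineage filter. Metadata carry site, round, season, category,
leaf mass (log-normal around 2 g) and the 8 mL suspension volume.

Because abundances are compositional, boosting indicator taxa in one
category necessarily depresses every other taxon's *relative* abundance
there. Non-boosted taxa therefore genuinely differ between categories in
the default community; only the all-multipliers-1 configuration is a true
null. The generator does not model sequencing error, chimeras, taxon-taxon
correlation, or zero inflation beyond what the Dirichlet-multinomial
produces.

## Pollution series

Daily site series for BC, PM2.5, PM10, NO₂ and O₃ are a site mean plus a
sinusoidal seasonal component plus Gaussian noise (25% of the mean),
floored at 0. Peak days encode the observed phenology: BC and NO₂
mid-winter, particulate matter late winter, O₃ mid-summer (exactly
anti-phased with NO₂). Site means default to the field values, so the
simulated site ranking reproduces the pollution gradient.

## Community statistics

* **Filtering.** Samples with fewer than 500 reads are dropped (strict
  inequality); taxa whose lineage contains "Chloroplast" at any rank
  (case-insensitive) are removed before analysis.
* **Transform.** S(x) = log₁₀(x+1) per cell, then each sample column is
  scaled to sum to 10⁶. Beta diversity is computed on this transformed
  matrix (scaling precedes distance computation); all-zero samples are
  rejected rather than silently propagated.
* **Shannon H** uses the natural log (the convention of the standard
  community-ecology toolchain); a `base` flag converts.
* **Rarefaction** subsamples reads without replacement via multivariate
  hypergeometric draws; tests verify the Monte-Carlo mean against the
  closed form Σᵢ (1 − C(N−nᵢ, d)/C(N, d)).
* **Bray–Curtis** is the literal formula, validated against an independent
  reference implementation. The triangle inequality is not asserted — it
  does not hold for Bray–Curtis in general.
* **PCoA** eigendecomposes −½ J D² J. Negative eigenvalues (expected for a
  semi-metric) are reported without Cailliez/Lingoes correction;
  coordinates use the k largest positive eigenvalues, with k reduced (and
  warned) when fewer exist.
* **NMDS** minimises Kruskal stress-1 with isotonic regression of
  configuration distances on the dissimilarity order and Guttman-transform
  updates; 20 restarts by default (the first from the PCoA configuration,
  the rest random and seeded), 300 iterations, stress-change tolerance
  1e-7. Non-convergence returns the best configuration flagged
  `converged=False`.
* **ANOSIM** R = (r̄_between − r̄_within)/(M/2) on tie-averaged ranks of
  the M = n(n−1)/2 dissimilarities. **PERMANOVA** is the one-factor
  distance partition (SS_total = Σd²/n; within-group sums scaled by group
  size) with pseudo-F and R². Permutation p-values include the observed
  statistic: p = (1 + #{R* ≥ R})/(1 + B), so p is never 0. An exhaustive
  mode enumerates all distinct label permutations for small n. One caveat
  carried over from the field presentation: ANOSIM's statistic is R, even
  where the field convention labels it "R²"; this package reports R and
  leaves the labelling discrepancy documented rather than resolved.
  Permutation p-values live on the grid {1/(B+1), …, 1}; calibration
  checks therefore use the randomized PIT p − V/(B+1) (V ~ U(0,1)), which
  is exactly U(0,1) under the null, instead of comparing discrete p-values
  against a continuous uniform.

## Indicator taxa

Counts are aggregated to a rank (unclassified entries pooled under
`unclassified_<parent>`; totals conserved) and expressed per million. The
screen is a per-taxon Kruskal–Wallis test at raw p < 0.05 (constant taxa
excluded with a note). Candidates are scored over 30 stratified bootstrap
subsamples of two-thirds of each class: per bootstrap, an all-class LDA is
fitted with a relative ridge (1e-6 × mean within-scatter diagonal) on the
candidate features, and a feature's raw effect is the mean of (a) its
largest absolute between-class mean difference and (b) the largest
absolute between-class difference of its contribution w·μ along the first
discriminant axis. The score is log₁₀ of the bootstrap-mean raw effect,
floored at 1 so scores are non-negative; rows with score ≥ 2 (≥ 100
per-million units of effect) form the indicator table, with the full
pre-filter scores retained. Enrichment is assigned one-vs-rest by highest
class mean; an all-class discriminant is the default (a one-vs-rest
variant would fit each class against the pooled rest — with three
balanced classes the all-class fit is the natural multigroup choice). The
LEfSe subclass (pairwise Wilcoxon) stage is omitted: the design defines no
subclasses.

Two properties of this construction matter for interpretation. First,
because the screen uses unadjusted p-values, about α of truly-null taxa
pass it, and at per-million scale those that pass usually clear the
score-2 threshold — so the expected false-report rate under a complete
null is near the screen's α (~4–5% measured), not zero. Second, in the
default effect community the compositional closure described above makes
non-boosted taxa genuinely category-dependent, and reporting them is
correct behaviour, not error. Tests therefore assert ≥ 80% recovery of
planted indicators with their planted category, monotonicity of the score
in the planted fold change, and a reported fraction under a complete null
bounded by the screen level with Monte-Carlo slack.

## Group comparisons

One-way ANOVA plus all-pairs Welch t-tests (pooled-variance mode behind a
flag; two-sided throughout), corrected by Bonferroni or Benjamini–Hochberg.
Site tests pool observations across rounds. Significance letters follow
the field-table convention: site i is letter `u`+i, and each site lists
the letters of sites it differs from at adjusted p < 0.05.

## Pipeline and I/O

`run_pipeline` chains simulate → detect → transform → test → indicators
from one seeded config; per-stage seeds are spawned from the master seed,
and the manifest records parameters and SHA-256 checksums of every output,
so identical configs give identical checksums. Tables are TSV, stacks
per-channel multi-page TIFF (pages along z), truth and manifests JSON.
Readers validate schemas (negative or non-integer counts, missing metadata
columns, asymmetric distance matrices) and name the offending cell.

## Problem sizes

Defaults were chosen for desk-scale runs: calibration suites use 24-sample
single-round campaigns with 40 taxa and 99 permutations (200 replicates);
the effect-ordering suite uses the full 192-sample design over 50
replicates; detector validation uses 50 seeded 64 × 64 × 35 stacks. The
complete test suite runs in well under a minute of CPU-minutes scale
(~40 s), the acceptance script in ~25 s.

## Known limitations

* The detector assumes co-registered channels and voxel-identical overlap;
  no tolerance radius, spectral unmixing, deconvolution or sub-voxel
  localisation.
* PERMANOVA is one-factor only; no nested/mixed designs, and no
  phylogenetic (UniFrac-type) metrics.
* The LDA effect-size formula is a stated construction validated by
  planted-truth recovery and monotonicity, not by numeric agreement with
  any external score list.
* Synthetic communities are exchangeable within site × round groups; real
  campaigns have spatial and temporal autocorrelation the generator does
  not emulate, so passing tests demonstrate correctness of the statistics,
  not field-level power.
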
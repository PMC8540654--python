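# phylloplane

Analysis pipeline linking ambient air pollution to ivy-leaf (phylloplane)
microbial communities. The package implements the two quantitative cores of
such a field campaign and exercises them on seeded synthetic data:

1. **Black-carbon (BC) particle counting** in two-channel microscope
   z-stacks of leaf-wash suspensions. BC particles emit in both the narrow
   second-harmonic generation band and the broad autofluorescence band,
   while autofluorescent debris emits in only one. Each channel is
   thresholded at 0.1% below its stack-wide intensity maximum, the two
   masks are intersected voxelwise, and particles are counted as 3D
   connected components of the overlap:

   load (particles · g⁻¹) = mean(stack counts) / V_image × V_susp / m_leaf

   with V_image the imaging volume (µm³), V_susp the wash-suspension volume
   (1 mL = 10¹² µm³) and m_leaf the washed leaf mass (g).

2. **Community statistics** from ASV count tables: sample filtering
   (< 500 reads), chloroplast removal, S(x) = log₁₀(x+1) scaling with
   per-million depth normalisation, Shannon diversity H = −Σ pᵢ ln pᵢ,
   rarefaction, Bray–Curtis dissimilarity d = Σ|a−b| / Σ(a+b), PCoA and
   NMDS ordination, ANOSIM / one-factor PERMANOVA permutation tests, and
   LEfSe-style indicator taxa (Kruskal–Wallis screen at p < 0.05, then a
   bootstrapped LDA effect size; log₁₀ scores ≥ 2 reported).

A synthetic-data module generates every input with the statistical
structure the analysis assumes — the 6-site × 8-round study design with
three BC-load categories (bcL/bcM/bcH), Dirichlet-multinomial communities
whose BC-category effect exceeds the seasonal effect, z-stacks with planted
coincident particles and single-channel confounders, and daily pollutant
series with anti-phased NO₂/O₃ seasonality — so every stage is testable
against planted ground truth.

## Worked example

```python
import phylloplane as pp

design = pp.StudyDesign()
print(pp.enumerate_design(design))
# DesignSummary(n_sites=6, leaves_meta=3840, leaves_bc=480, total_leaves=4320,
#               pooled_samples=192, bc_samples=96, zstacks=480, slices_per_sample=175)

# detect planted BC particles in a synthetic stack pair
pair, truth = pp.simulate_zstack_pair(n_particles=10, n_confounders=5, seed=1)
print(pp.detect_particles(pair).count, truth.n_particles)   # 10 10

# community effect sizes on one simulated campaign
counts, tax, meta, _ = pp.simulate_community(design, pp.CommunitySimConfig(seed=3))
table = pp.remove_taxa_by_lineage(pp.filter_samples(pp.AsvTable(counts, tax)))
d = pp.bray_curtis(pp.transform_counts(table))
meta = meta.loc[d.index]
print(pp.anosim(d, meta["bc_category"], n_perm=99, seed=1).statistic)  # 0.396
print(pp.anosim(d, meta["season"], n_perm=99, seed=1).statistic)      # 0.034
```

The BC-category grouping explains far more of the Bray–Curtis structure
(ANOSIM R ≈ 0.40) than the seasonal grouping (R ≈ 0.03), the ordering the
pipeline is designed to detect.

The numbered scripts under `analysis/` run the whole campaign:
`01_study_design.py` (design arithmetic), `02_simulate_campaign.py`
(synthetic data → `scratch/campaign/`), `03_detect_bc_particles.py`
(particle calls, per-gram loads, category fold changes),
`04_community_diversity.py` (alpha/beta diversity, ordination, permutation
tests), `05_indicator_taxa.py` (indicator taxa at four ranks) and
`06_pollution_trends.py` (pollutant site means and seasonality). Summary
tables land in `results/`.

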
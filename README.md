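# hexki67

Spatial intratumoral heterogeneity of Ki67 expression from digital-pathology
cell exports: hexagonal-grid subsampling, Haralick texture entropy,
cross-platform agreement statistics, and prognostic survival modeling.

## Who this is for

Digital-image-analysis (DIA) platforms such as HALO or Aiforia turn a
Ki67-stained whole-slide image into a table of tumor-cell centroids, each
classified Ki67-positive or Ki67-negative. The global Ki67% (share of
positive cells) summarises proliferation but ignores *where* the
proliferating cells are. This package quantifies the spatial variability of
Ki67 — a prognostic signal in ER+/HER2− breast cancer — and provides the
statistical machinery to test whether such a metric is reproducible across
DIA platforms and robust to how the tissue was sampled (surgical halves,
quadrants, or core-needle biopsies).

## The metric

1. Overlay a regular hexagonal grid (side 262.5 µm, per-tile area
   ≈ 1.79 × 10⁵ µm²) on the cell coordinates; tiles with fewer than 50
   cells are excluded as insufficiently sampled.
2. Compute each valid tile's Ki67-positive percentage and rank it into ten
   intervals (0–10%, >10–20%, …).
3. For every pair of adjacent valid tiles (hexagonal 6-neighborhood),
   record the bin pair in a symmetric 10 × 10 co-occurrence matrix with
   probabilities *p₍ᵢⱼ₎*.
4. Haralick features summarise the matrix; the headline metric is the
   entropy

   H = −Σᵢⱼ p₍ᵢⱼ₎ log₂ p₍ᵢⱼ₎  ∈ [0, log₂ 100 ≈ 6.64 bits],

   together with energy Σ p², contrast Σ (i−j)² p, dissimilarity Σ |i−j| p,
   homogeneity Σ p/(1+(i−j)²), and Ashman's bimodality
   D = |μ₁−μ₂| / √((σ₁²+σ₂²)/2) from a two-Gaussian fit to the tile
   percentages.

A spatially uniform tumor concentrates all adjacent-tile pairs in one bin
pair (H → 0); a patchwork of hot and cold regions spreads mass across the
matrix (large H).

Around the metric the package provides a method-agreement battery
(Spearman, ICC(3,1), Lin's CCC with bootstrap CI, Bland-Altman limits of
agreement, Wilcoxon signed-rank, Lilliefors normality), tissue-sampling
simulators (halves, quadrants, 1.2 × ≤12 mm vertical biopsy strips), and
survival modeling (log-rank-optimized dichotomization, Cox proportional
hazards with Efron ties, likelihood-ratio statistics, Harrell's C on a
held-out split). A seeded synthetic-cohort generator — uniform cell
positions, a smooth logistic positivity field with tunable heterogeneity
amplitude, a label-flip second "platform", and proportional-hazards
outcomes with planted hazard ratios — makes every stage testable without
patient data.

## Worked example

```python
from hexki67 import (PipelineConfig, SyntheticCohortSpec, generate_cohort,
                     case_texture, global_ki67_pct)

spec = SyntheticCohortSpec(n_cases=20, seed=7)
cohort = generate_cohort(spec)
cells = cohort.cells["platform1"]["case0001"]
tf = case_texture(cells, PipelineConfig())
print(f"Ki67% = {global_ki67_pct(cells):.2f}")
print(f"valid tiles = {tf.n_valid_tiles}, adjacent pairs = {tf.n_pairs}")
print(f"entropy = {tf.entropy:.3f} bits, energy = {tf.energy:.3f}, "
      f"Ashman D = {tf.ashman_d:.2f}")
```

prints

```
Ki67% = 8.82
valid tiles = 550, adjacent pairs = 1551
entropy = 1.842 bits, energy = 0.308, Ashman D = 1.58
```

This case has 50 000 cells on a 10 × 10 mm region; 550 hexagons pass the
50-cell filter and contribute 1551 adjacent pairs. Its Ki67% of 8.8% is
low and its entropy of 1.84 bits indicates mild spatial patchiness. Across
the 20-case cohort, entropies span 0.00–5.60 bits (median 3.66): cases
drawn with near-zero heterogeneity amplitude produce tiles that all fall
in one or two positivity bins (entropy near 0), while large amplitudes
spread tiles — and hence adjacent-tile pairs — across many bins.

## Command line

```bash
hexki67 synth --seed 1 --out-dir cohort/          # cell CSVs + clinical CSV
hexki67 metrics cohort/cells_platform1.csv        # full-section metrics
hexki67 subsample cohort/cells_platform1.csv      # halves/quadrants/biopsies
hexki67 agree region_metrics.csv                  # agreement battery
hexki67 prognosis region_metrics.csv cohort/clinical.csv
hexki67 run-all --seed 1 --out-dir out/           # everything + manifest
```

All outputs are CSV plus a JSON run manifest; a flat TOML file mirroring
`PipelineConfig` can be passed via `--config`.

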
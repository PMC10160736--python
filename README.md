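# pbvoom

Differential expression for pseudo-bulk scRNA-seq data with **group-aware
variance modeling**, plus a correlated negative-binomial single-cell
simulator and an FDR/power benchmark harness.

## The problem

Pseudo-bulk differential expression sums the UMI counts of all cells of a
sample (for one cell type) into a single column and analyzes the resulting
gene-by-sample count matrix with bulk RNA-seq machinery. The standard voom
pipeline fits, per gene *g*, a linear model E(y_g) = Xβ_g on log-CPM values,
smooths √(residual SD) against average log-count with LOWESS, and converts
the fitted curve lo(·) into observation precision weights

    w_gi = lo(λ̂_gi)⁻⁴

for weighted least squares with empirical-Bayes moderated t-tests. This
assumes **one** mean-variance trend for all samples. Real pseudo-bulk
cohorts are frequently *group-heteroscedastic*: disease groups with more
biological variation sit on a higher trend than stable control groups.
Pooling them under-estimates the variance of the noisy groups (inflated
false discovery rates in their comparisons) and over-estimates the variance
of the quiet groups (lost power). Two remedies are implemented:

- **voomQWB** — voomWithQualityWeights with *blocked* sample weights: a
  variance factor exp(γ_i) per experimental group (identical within a
  group), estimated by a REML-style gene-wise iteration, giving combined
  weights w*_gi = w_gi / exp(γ̂_i). Each group's trend is a parallel
  up/down shift of the common voom trend.
- **voomByGroup** — the expression matrix and design are subset per group
  and a *separate* LOWESS trend is fitted for each, so the trends can
  differ in shape, not just height. Per-group weights w_gic are reassembled
  into w#_gi. Groups with ≤ 2 samples fall back to the overall trend (the
  `dynamic` option). Group-wise common BCVs (√ of the common NB dispersion,
  Cox–Reid adjusted profile likelihood) annotate the diagnostic plots.

The simulator generates single-cell counts with marginal NB distributions
and intra-subject correlation ρ through a Gaussian copula (equicorrelated
normals → gamma quantiles → Poisson), so that aggregating K cells yields
pseudo-bulk dispersion approximately φ_agg = ρ·φ_sc + (1−ρ)/N with
N = (ΣLᵢ)²/ΣLᵢ². Four benchmark scenarios (4 groups × 3 samples, 10,000
genes, 50 spiked genes per group at log2FC 2) cover heteroscedastic
biology, a homoscedastic null, unequal cell numbers, and both combined.

## Worked example

```python
import numpy as np
from pbvoom import (scenario_preset, simulate_dataset, aggregate_cells,
                    filter_genes, tmm_norm_factors, DesignMatrix,
                    voom_by_group, de_table, decide_de)

cfg = scenario_preset("scenario1", seed=2)      # 4 groups x 3 samples
cells, truth = simulate_dataset(cfg)
pb = tmm_norm_factors(filter_genes(aggregate_cells(cells), min_total=30))

design = DesignMatrix.from_groups(pb.group_labels)   # means coding
wle = voom_by_group(pb, design, group=pb.group_labels)
print({g: round(b, 3) for g, b in wle.group_bcv.items()})

contrast = np.array([-1.0, 1.0, 0.0, 0.0])           # group2 - group1
table = de_table(wle, contrast)
called = decide_de(table, cutoff=0.05)
tp = len(called & truth.de_for_comparison("group1", "group2"))
print(f"{len(called)} genes at adj.p<=0.05, {tp} true positives")
```

Output:

```
{'group1': 0.187, 'group2': 0.204, 'group3': 0.243, 'group4': 0.258}
67 genes at adj.p<=0.05, 63 true positives
```

The per-group BCVs increase from group 1 to group 4, mirroring the
increasing biological variation the scenario encodes; of the 67 genes
called for the low-variation comparison, 63 are truly differential
(observed FDR 0.06 at the nominal 0.05 cut-off).

The same pipeline is scriptable from the shell:

```bash
pbvoom simulate --scenario scenario1 --seed 1 --out sim/
pbvoom aggregate --counts sim/rep1/matrix.mtx \
    --cell-meta sim/rep1/cell_meta.tsv --sample-meta sim/rep1/sample_meta.tsv \
    --min-cells 50 --out pb.tsv
pbvoom de --counts pb.tsv --method voombygroup --contrast group2-group1 \
    --plot combine --out de/
pbvoom evaluate --scenario scenario1 --reps 10 --seed 7 --out bench/
```

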
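# protnorm

Benchmarking of normalization and batch-effect correction methods for
protein-level quantification data (label-free and TMT proteomics).

Mass-spectrometry intensity tables carry systematic non-biological biases —
per-sample loading and instrument drift, intensity-dependent distortions,
and, in multi-run TMT studies, batch effects. Many normalization methods
exist, most inherited from microarray analysis, and the usual way of
choosing one (pick whatever reduces intragroup variation most) does not
guarantee good downstream results: a method can tighten replicates while
biasing fold changes or flooding the differential-expression (DE) call set
with false positives. `protnorm` is a toolkit for comparing normalization
strategies *on their downstream consequences*: it applies a panel of
methods to one dataset, quantifies intragroup/intrabatch variation, runs DE
tests, and scores every method against spike-in ground truth — or, when no
truth exists, compares methods by DE counts and the Jaccard overlap of
their DE sets.

## What is implemented

**Normalization** (all returning log2-scale matrices with missingness
preserved): mean, median, global mean/median, MAD, quantile, robust linear
regression (Rlr, RlrMA, RlrMACyc), loess (LoessF, LoessCyc), TMM, VSN
(affine-arsinh variance stabilization, x ↦ arsinh(a_j + b_j x)/ln 2),
Normics (median and VSN variants on an invariant-protein set), EigenMS
(SVD residual-trend removal with a permutation test), RobNorm
(density-power-weighted fit of x_ij = μ_i + s_j + ε_ij), plus the
unnormalized log2 baseline.

**Batch correction**: internal reference scaling (IRS) on pooled TMT
reference channels, and limBE — per-protein linear-model removal of
sum-to-zero-coded batch effects — composable before or after any
normalization.

**Evaluation**: pooled median absolute deviation
PMAD_g = (1/n) Σ_i MAD_ig, intragroup Pearson correlation, silhouette
coefficients S_j = (b_j − a_j)/max(a_j, b_j) on the first three principal
components (condition- and batch-wise), hierarchical clustering.

**DE testing**: an empirical-Bayes moderated t-test with scaled-F variance
shrinkage (t = logFC/(s̃·√(1/n₁+1/n₂)), s̃² = (d₀s₀² + d s²)/(d₀+d)), the
reproducibility-optimized test statistic (ROTS,
d = |x̄₁−x̄₂|/(α₁+α₂·SE) tuned by bootstrap top-list overlap), and
Benjamini–Hochberg control at 0.05.

**Scoring**: TP/FP/TN/FN (a spike-in called DE is a TP, a background
protein called DE is an FP), F1, FPR, tie-corrected AUC, logFC accuracy
against expected log2 concentration ratios, J(A,B) = |A∩B|/|A∪B|
intersection analysis, and method ranking by median F1 with paired
Wilcoxon signed-rank tests.

**Synthetic data**: seeded generators for spike-in designs (constant
background + known concentration shifts), sample-level systematic shifts,
multi-batch TMT layouts with pooled reference channels, and MAR/MNAR
missingness — every study condition used by the tests is a named scenario.

## Worked example

```python
import pandas as pd
import protnorm as pn
from protnorm.de import moderated_t

ds, truth, _ = pn.simulate_scenario("default", seed=1)   # 3000 x 8 spike-in
scores = {}
for method in ("log2", "median", "mad", "robnorm"):
    res = pn.normalize(ds, method)
    de = moderated_t(res.matrix, ds.conditions, "B", "A")
    scores[method] = pn.score_method(de, truth, "B", "A")
report = pd.DataFrame(scores).T
print(report[["F1", "FPR", "AUC", "background_median_logfc",
              "spikein_median_bias"]].round(3))
```

```
            F1    FPR    AUC  background_median_logfc  spikein_median_bias
log2     0.836  0.044  1.000                    0.373                0.374
median   0.906  0.007  0.996                   -0.094               -0.093
mad      0.903  0.008  0.996                   -0.025               -0.759
robnorm  0.951  0.003  0.999                   -0.013               -0.012
```

Reading the table: the unnormalized baseline (`log2`) leaves the injected
per-sample shifts in place — its background median logFC of 0.37 should be
zero, and its FPR is an order of magnitude above the normalized methods.
Median normalization removes the shift; RobNorm additionally resists the
influence of the regulated spike-ins and scores best. MAD shows the
characteristic pathology of scale-standardizing every sample: background
accuracy looks fine, but spike-in fold changes are compressed by 0.76 log2
units (`spikein_median_bias`), which in real data suppresses DE calls at
any |logFC| threshold. Reducing intragroup variation (MAD is the best
method by PMAD reduction) is evidently not the same thing as being the
best normalization — which is the point of benchmarking downstream.

The same workflow is scriptable from a shell:

```sh
protnorm simulate  --scenario default --seed 1 --out run/sim
protnorm normalize --intensities run/sim/intensities.tsv \
                   --metadata run/sim/metadata.tsv --all --out run/norm
protnorm benchmark --normalized-dir run/norm --metadata run/sim/metadata.tsv \
                   --truth run/sim/truth.tsv --contrast B-A --out run/bench
```

`run/bench/spikein_scores.tsv` then holds the full per-method
F1/FPR/AUC/logFC table, `de_counts.tsv` the up/down counts and
`jaccard.tsv` the DE-set overlap matrix. Every subcommand writes a
`manifest.json` with the resolved parameters and seed; identical
config + seed reproduces byte-identical outputs.

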
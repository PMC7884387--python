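# paleoattrib

Quantitative attribution of isolated hominin teeth and associated lithic
assemblages. When a single fossil molar has to be assigned to a tooth
position (M₁ vs M₂) and a population (e.g. Neanderthals vs Pleistocene or
Holocene *Homo sapiens*), and the associated stone tools compared against
reference assemblages, the argument rests on a small set of quantitative
tools. This package implements that toolchain as a tested, reusable
library with synthetic-data generators for every input, so the whole
chain runs end to end without access to restricted comparative
collections.

It is aimed at dental anthropologists and lithic analysts who want the
statistics behind such attributions to be reproducible and scriptable.

## What it computes

**Adjusted Z-scores.** A lone specimen compared against a comparative
sample of size *n* with mean X̄ and sample SD:

    z_adj = (x − X̄) / ( t₀.₉₇₅,ₙ₋₁ · √( SD² · (1 + 1/n) ) )

The denominator is the half-width of the two-sided 95% Student-*t*
prediction interval, so |z_adj| ≤ 1 exactly when the specimen lies within
95% of the group's variation — at any *n*, unlike the classical Z-score.
Crown index (100·B/L) and crown area (L·B) are included.

**3D dental tissue proportions.** From a segmented voxel volume
(enamel/dentine/pulp): cervical best-fit plane (total least squares),
parallel occlusal cut, lateral average enamel thickness
(3D LAET = lateral enamel volume / EDJ surface area, mm) and the
scale-free 3D LRET = 100·LAET/(lateral dentine+pulp volume)^⅓. The
half-maximum-height (HMH) threshold operator for two-material grayscale
segmentation is provided.

**Volumetric bifurcation index.** Taurodontism quantified by splitting
the root at the interradicular surface:
VBI = V_cervix/(V_cervix + V_branch) × 100, with the bifurcation plane
located automatically (first voxel layer whose root cross-section splits
into ≥ 2 connected components) or supplied explicitly.

**Geometric morphometrics.** Arc-length semilandmark curve resampling,
generalized Procrustes analysis (translation, unit centroid size,
least-squares rotation, no reflections), PCA of Procrustes residuals,
between-group PCA with leave-one-out cross-validation, CVA on the PCs
explaining ~90% of variance, a-posteriori projection of an unknown
specimen, Mahalanobis posterior probabilities, and per-axis allometry
regressions on centroid size. Estimators follow the scikit-learn
`fit`/`transform`/`predict` protocol.

**Lithic attribute analysis.** Elongation, proximal/distal shape,
flattening and tip cross-sectional area (TCSA = distal width × distal
thickness); rank-based ordered-quantile normalization, centring/scaling,
PCA ordination, and convex-hull overlap summaries between assemblages.

## Worked example

```python
import paleoattrib as pa
from paleoattrib.io_core import ComparativeStats
from paleoattrib import synthetic as syn

# 1. Is a 12.3 mm mesiodistal length inside a group's 95% variation?
st = ComparativeStats("WANEA", "MD_length", mean=11.2, sd=0.55, n=14)
pa.adjusted_z(12.3, st)          # 0.894  -> inside the 95% band (|z| <= 1)
pa.crown_index(11.0, 12.5)       # 88.0   (% , breadth/length x 100)

# 2. Root taurodontism from stem/branch volumes (mm^3)
pa.vbi(502.6, 234.2)             # 68.2   (%)

# 3. Shape classification on synthetic grouped semilandmarks
sample = syn.simulate_shape_groups(syn.ShapeSimSpec(n_per_group=20, seed=20210215))
aligned = pa.gpa(sample.configs)             # generalized Procrustes
res = pa.cv_bgpca(aligned, sample.labels)    # leave-one-out bgPCA
res.summary                                  # {'A': 100.0, 'B': 100.0}

pc = pa.pca(aligned)
m = pa.select_pcs(pc.explained, 0.90)        # 32 PCs -> 91.3% of variance
model, loo = pa.cva(pc.scores[:, :m], sample.labels)
loo.summary                                  # {'A': 100.0, 'B': 100.0}
```

The adjusted Z-score of 0.894 says the hypothetical specimen sits inside
the group's 95% prediction band; the two LOO summaries report per-group
correct-classification percentages for groups whose mean-shape offset is
ten times the landmark noise — at that separation both classifiers should
be (and are) essentially perfect.

A command-line interface mirrors the library:

```sh
paleoattrib vbi --vcervix 502.6 --vbranch 234.2     # "VBI = 68.2%"
paleoattrib simulate lithics --seed 3 --n 25 --out artefacts.csv
paleoattrib lithics --table artefacts.csv --out results/lith
paleoattrib run --config run.yaml                   # full attribution report
```

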
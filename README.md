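# pamorph

Morphometry of the central pulmonary arteries from CT pulmonary angiography
(CTPA), and the downstream diagnostic statistics for pulmonary hypertension
(PH).

Pulmonary hypertension is defined hemodynamically — mean pulmonary arterial
pressure (mPAP) > 20 mmHg at right heart catheterization (RHC) — but
catheterization is invasive, so imaging surrogates matter.  The classical
surrogate is the main pulmonary artery diameter measured on one axial slice;
this package implements the full three-dimensional alternative and the
analysis used to compare the two:

* **Measurement chain** — segment the contrast-filled lumen by Hounsfield
  windowing (−200…500 HU) plus seeded region growing; extract and smooth a
  centerline tree with 1 mm control points; then compute, per artery (main,
  right, left — MPA/RPA/LPA):
  * `D` — the diameter on a 10 mm axial maximum-intensity-projection slab,
    measured 15 mm from the bifurcation perpendicular to the vessel's
    in-plane long axis (full-width-at-half-maximum edges);
  * `A` — the lumen cross-sectional area on the plane orthogonal to the
    centerline at that same point;
  * `V` — the volume, `V = Σ A(sᵢ)·Δsᵢ` over the centerline control points
    (the sum of per-slice areas at 1 mm spacing), with a configurable
    exclusion margin at the valve and bifurcation ends.
* **Statistics** — Shapiro–Wilk-gated two-group tests (Student t /
  Wilcoxon rank-sum), Pearson χ² / Fisher exact for 2×2 tables,
  normality-gated Pearson/Spearman correlation, ROC analysis with
  Youden-optimal cutoffs (sensitivity, specificity, PPV, NPV, accuracy),
  DeLong tests for paired AUCs, decision-curve analysis (net benefit
  `TP/N − (FP/N)·pt/(1−pt)`), and forward stepwise linear regression for
  predicting mPAP/SPAP/DPAP from the nine measurements.
* **Synthetic data** — since no patient data ship with the package, two
  generators provide fully characterized inputs: voxel phantoms of tubes and
  bifurcating MPA→RPA/LPA trees with *analytic* ground truth (centerline,
  area profile, volume), and two-group patient cohorts with configurable
  group distributions and measurement–pressure correlations.

## Worked example

Measure a bifurcating phantom (trunk radius 18 mm, branch radii 12 mm,
rasterized at 1 mm with partial-volume blending) end to end:

```python
from pamorph.phantom import make_pa_tree_spec, rasterize_phantom
from pamorph.segmentation import segment_vessel
from pamorph.core_io import Point3D
from pamorph.centerline import skeletonize, extract_tree, CenterlineConfig
from pamorph.morphometry import measure_all, MeasurementConfig

spec = make_pa_tree_spec(spacing=(1.0, 1.0, 1.0))
volume, truth = rasterize_phantom(spec)
seed = Point3D.from_array(spec.tubes["trunk"].curve.point(30.0))
mask = segment_vessel(volume, seed)
tree = extract_tree(skeletonize(mask), CenterlineConfig(), mask=mask, seed=seed)
m = measure_all(volume, mask, tree, MeasurementConfig(exclusion_margin=18.0))
for k, v in m.as_dict().items():
    print(f"{k:6s} {v:10.2f}")
```

```
D_MPA       36.05
A_MPA     1016.44
V_MPA    24419.11
D_RPA       24.16
A_RPA      453.75
V_RPA    12896.37
D_LPA       24.22
A_LPA      452.12
V_LPA    13180.87
```

The true trunk diameter is 36 mm (area π·18² ≈ 1017.9 mm²) and the branch
diameters 24 mm (area ≈ 452.4 mm²): every quantity is recovered within ~1%.
Volumes cover the trimmed extent between the exclusion margins, which
`measure_all` records in `m.extents`.

Generate a 59-patient cohort (18 non-PH / 41 PH) and rank the MPA markers:

```python
from pamorph.cohort import CohortConfig, generate_cohort
from pamorph import stats as st

df = generate_cohort(CohortConfig(), seed=1)
print(st.roc_table(df, ["D_MPA", "A_MPA", "V_MPA"]).round(3).to_string(index=False))
```

```
marker  cutoff value   AUC      95% CI  sensitivity  specificity   PPV   NPV  Accuracy
 D_MPA        29.968 0.885 0.800~0.971        0.844        0.852 0.871 0.821     0.847
 A_MPA       844.780 0.862 0.767~0.958        0.812        0.852 0.867 0.793     0.831
 V_MPA     34418.802 0.956 0.909~1.000        0.969        0.852 0.886 0.958     0.915
```

The volume outranks the diameter and area, as expected from the cohort's
configured correlation structure (`r(V_MPA, mPAP) = 0.744` by default).

The same steps are available from the shell: `pamorph phantom | cohort |
segment | centerline | measure | stats | run` (see `pamorph --help`); `run`
executes a whole configured pipeline with a manifest and `--resume` support.

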
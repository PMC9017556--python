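# medsegmesh

Medical-image preprocessing, segmentation and tetrahedral reconstruction for
CT/MR-style grayscale volumes, built to be fully testable on synthetic
phantoms with known ground truth.  Intended for researchers prototyping
segmentation/meshing pipelines (e.g. for virtual-surgery or quantitative
anatomy work) who need every stage of the chain — intensity preparation,
contour extraction, volume meshing, quantitative scoring — in one place with
reproducible, seedable behavior.

## What it does

**Preprocessing** (`medsegmesh.preprocess`): CT-value mapping
`1000·(μ − μ_water)/μ_water`; the window/level display transform mapping
`[L − W/2, L + W/2]` linearly onto 8-bit gray; histogram equalization;
inter-slice trilinear interpolation; and two-step denoising for sequential
slices (z-median of window 5, then 3×3 weighted neighborhood averaging).

**Level-set segmentation** (`medsegmesh.levelset`): the core method.  A
contour is the zero level of φ evolving under the *local binary fitting*
(LBF) energy

    E(φ, f1, f2) = λ₁ ∬ K_σ(x−y) |I(y) − f1(x)|² H(φ(y)) dy dx
                 + λ₂ ∬ K_σ(x−y) |I(y) − f2(x)|² (1 − H(φ(y))) dy dx
                 + ν ∫ δ(φ)|∇φ| + μ ∫ ½(|∇φ| − 1)²

where f1, f2 are Gaussian-weighted local inside/outside intensity fits —
this is what makes the model robust to smooth multiplicative bias
("migration") fields, unlike the piecewise-constant (Chan–Vese) energy with
global means c1, c2, which is also provided for comparison.  The evolution
uses a per-pixel **variable time step** τ(x) = τ₀·g(x) with
g = 1/(0.5 + |∇(K∗I)|) + 1: three times the base step in flat regions,
close to the base step at edges, reconciling convergence speed with
boundary accuracy.  A multi-class wrapper segments k tissue classes by
per-class binary level sets combined by arg-max of φ.

**Classical segmenters** (`medsegmesh.classical_seg`): an ant-colony
pixel-clustering segmenter (per-pixel features V/G/Ne, pheromone-weighted
cluster assignment, inertial ant walks that deposit a pheromone field driven
by window similarity), seeded region growing, and k-means / FCM / KFCM
intensity-clustering baselines.

**Tetrahedral meshing** (`medsegmesh.tetmesh`): incremental (Bowyer–Watson)
Delaunay tetrahedralization with exact-arithmetic predicate fallback;
constrained Delaunay for closed triangulated surfaces with boundary recovery
(re-diagonalization flips, then Steiner points restricted to the constraint
entities) and "dyeing" flood-fill deletion of the exterior; sliver
elimination by 3-2 flips (type-1 configurations) and quality-maximizing
vertex relocation (type-2), never inverting an element.

**Phantoms & metrics** (`medsegmesh.phantom_eval`): disk and three-tissue
nested phantoms with calibrated Gaussian noise (std as % of the brightest
class mean) and multiplicative bias fields (40% → field spans [0.8, 1.2]);
the average overlap metric AOM = 2|V_m ∩ V_a|/(|V_m| + |V_a|) (the Dice
coefficient), SNR in dB, and a per-class evaluation report with greedy
best-overlap label matching.

## Worked example

Segment a 128×128 three-class tissue phantom with 3% noise and a 40% bias
field, then score it:

```python
from medsegmesh.phantom_eval import PhantomSpec, make_tissue_phantom, evaluate_run
from medsegmesh.levelset import segment_classes

img, truth = make_tissue_phantom(PhantomSpec(noise_percent=3, bias_percent=40, seed=1))
labels, _ = segment_classes(img, 3, seed=1)
print(evaluate_run(truth, labels).to_csv())
```

prints

```
class,aom
1,0.999796
2,1.000000
3,1.000000
overall,1.00
```

per-class AOM (class 1 = darkest tissue, 3 = brightest) and the overall
mean rounded to two decimals.  Mesh an L-shaped prism through its
triangulated boundary:

```python
from medsegmesh import tetmesh as tm
from medsegmesh.phantom_eval import make_volume_fixtures

pts, cons, vol = make_volume_fixtures("Lprism")   # analytic volume 0.75
mesh = tm.constrained_delaunay(pts, cons)
q = tm.mesh_quality(mesh)
print(f"tets={q['n_tets']}  volume={q['total_volume']:.12f}  min_dihedral={q['min_dihedral']:.2f} deg")
```

prints

```
tets=37  volume=0.750000000000  min_dihedral=9.76 deg
```

— the dyed mesh reproduces the analytic enclosed volume to machine
precision even though the solid is concave.

The same stages are scriptable from the shell:

```sh
medsegmesh phantom tissue --noise 3 --bias 40 --seed 1 -o img.tif -m truth.tif
medsegmesh segment levelset img.tif --classes 3 --seed 1 -o pred.tif
medsegmesh evaluate --truth truth.tif --pred pred.tif -o report.csv
medsegmesh phantom fixtures --name Lprism -o lp
medsegmesh mesh --points lp.node --surface lp.poly --optimize -o lpmesh
```

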
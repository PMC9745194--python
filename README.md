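# florashape

Color + shape-distribution descriptors for 3D flower meshes: feature
extraction, importance-based feature weighting, and chi-square
retrieval/classification.

## The problem

Classifying flower cultivars (the motivating case is Chinese rose
varieties) from 2D photographs is brittle: a single view hides most of
the corolla geometry, and illumination shifts the apparent color.  A
colored 3D scan of the flower head carries the full morphology, but it
needs a compact, comparable representation.  `florashape` builds such a
representation for watertight-ish triangle meshes with per-vertex RGB
colors, and uses it for content-based retrieval and nearest-neighbor
classification of flower species.

## The descriptor

Given a mesh, the pipeline normalizes it (centroid to the origin,
maximum centroid-to-vertex radius to 1) and computes **ten features**:

* **Six shape-distribution histograms** — 400-bin normalized histograms
  of a geometric measure on 4000 random surface-point tuples each:
  * D1 — distance of a point to the centroid,
  * D2 — distance between two points,
  * D3 — area of a three-point triangle,
  * A3 — angle at the middle point of a triple,
  * D4 — volume of a four-point tetrahedron,
  * C1 — curvature (inverse circumradius) of the circle through three
    points.

  Sampling is **stratified**: the unit ball is split into three shells
  of equal volume (boundaries (1/3)^⅓ ≈ 0.7 and (2/3)^⅓ ≈ 0.87,
  the stamen / petal-body / petal-rim layers), and tuples are drawn
  from the layers in turn, so the thin outer petal rims are not
  swamped by the bulky interior.
* **Sharpness** S7 = max(disₙ)/min(disₙ) over vertex-to-centroid
  distances — spikes and scan defects push it above 1.
* **Contour** P8 = V_flower / V_sphere, the mesh volume over its
  minimum-enclosing-sphere volume — a fullness measure in (0, 1].
* **Color indicator** C9 ∈ {1..8} — after rejecting leaf-green sample
  points (RGB distance to green (191,212,143) below a threshold N), the
  reference color (red, yellow, pink, black-red, blue, green, white,
  orange) with the minimum mean RGB distance; plus the **color purity**
  Cp, the fraction of retained points individually nearest to C9.

Features are ranked by **random-forest out-of-bag permutation
importance** — V(Xⱼ) = mean over trees of (OOB error after permuting
group j − baseline OOB error), with all 400 bins of a histogram
permuted jointly — and combined with exponentially decaying rank
weights (0.28, 0.19, 0.14, 0.11, 0.08, 0.07, 0.05, 0.04, 0.02, 0.02),
or uniform 0.1 weights for comparison.  Two descriptors are compared by
the weighted per-feature chi-square distance

    d(A, B) = Σ_f  w_f · Σ_i (A_f(i) − B_f(i))² / (A_f(i) + B_f(i)),

mapped to a similarity Sim = (max d − d)/(max d − min d) over the
collection.

Because real rose-scan collections are rarely shareable, the package
includes a parametric **synthetic flower generator** (petal lobes on a
deformed sphere, stamen core, openness / fullness / damage / color
controls with known ground truth) so every stage is testable offline.

## Worked example

```bash
python examples/extract_descriptor.py
```

```
mesh: 1051 vertices, 2048 faces
S7 (sharpness, max/min centroid distance) = 5.931
P8 (contour, volume / enclosing sphere)   = 0.425
C9 (color indicator, 1..8)                = 3  (3 = pink)
Cp (color purity of retained samples)     = 1.000
D1: 400 bins on [0, 1.000], mode near 0.904
...
```

S7 ≈ 5.9 reflects the spread between the stamen core and the petal
tips; P8 ≈ 0.43 says the bloom is about half open; C9 = 3 with
Cp = 1.0 identifies a purely pink flower; the D1 mode near 0.9 is the
petal shell of the normalized head.  The other examples cover retrieval
(`retrieve_similar.py` — the self-match scores 100 % similarity and
same-species flowers follow), importance ranking
(`rank_importance.py`), and the three-variant evaluation
(`evaluate_benchmark.py` — on a ten-class benchmark, ablating the
color features drops mean 1-NN accuracy from 100 % to 93.3 % and
retrieval PR AUC from 0.98 to 0.83).

The same operations are available as a CLI:

```bash
florashape generate --classes 15 --per-class 40 --out meshes/
florashape extract meshes/*.ply --out descs/
florashape index --descriptors descs/ --manifest meshes/manifest.csv --out index.jsonl
florashape retrieve --index index.jsonl --query descs/class_00_000.json --k 6
florashape evaluate --index index.jsonl --out metrics/
florashape importance --index index.jsonl
```

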
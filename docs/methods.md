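# Methods

This note records the modeling choices behind `florashape`: what is
computed, under which assumptions, which defaults matter, and where the
design was genuinely open.

## Input model and normalization

The unit of analysis is a triangle mesh of a single flower head with
optional per-vertex RGB colors (PLY vertex-color dialect; OBJ accepted
shape-only or with a CSV color sidecar).  Scans are typically *open*
surfaces (petals have no thickness), so nothing assumes watertightness;
where it matters (volume) the convention is stated below.

The centroid is the arithmetic mean of the vertices — not the
area-weighted surface centroid — because the downstream distances are
defined on vertices; an area-weighted alternative is available via
`compute_centroid(mesh, area_weighted=True)` for very uneven
tessellations.  Normalization translates the centroid to the origin
and divides by the maximum centroid-to-vertex distance ("maximum
radius scaling"), after which every mesh sits in the unit ball and all
descriptors are invariant to placement, orientation and size.

## Surface sampling and stratification

Sample points are drawn area-weighted per face with uniform barycentric
placement; colors are barycentrically interpolated and rounded.  The
unit ball is split into three equal-volume shells with boundaries
(k/3)^(1/3), k = 1, 2 — computed exactly rather than hard-coding the
rounded 0.7 / 0.87.  Layer intervals are half-open below
([0, r₁), [r₁, r₂), [r₂, ∞)) so the layers partition every radius;
the published interval notation "(0, 0.7)" etc. leaves the boundaries
ambiguous and a total partition drops no points.

Tuples for the shape functions are drawn layer by layer in a fixed
out → mid → in round-robin, with each tuple wholly inside one layer
(`cross_mode="intra"`); this makes every histogram mix the intra-layer
geometry of all three shells equally.  "Crossing the layers in turn"
admits a second reading — the points *within* one tuple rotating
through the layers — which is available as `cross_mode="inter"`, but
mixes inter-layer distances into every histogram and is not the
default.  Within a layer, points are drawn uniformly without
replacement inside a tuple and with replacement across tuples.  A layer
with fewer points than the tuple size falls back to the whole sample
pool; a layer with no points is skipped from the cycle.

Default sample budget: 4000 surface points shared as the sampling pool,
and 4000 tuples per shape function (the per-function reading of the
published point counts; 4000 tuples per function is still cheap).  The
alternative reading — 4000 tuples split across the six functions — was
rejected as under-sampling the 400-bin histograms.

## Shape-distribution functions

D1 pairs one random point with the centroid; D2, D3, A3, D4, C1 use
2, 3, 3, 4, 3 random points.  D3 is the raw triangle area and D4 the
raw tetrahedron volume; the classical square-root / cube-root
linearization of prior shape-distribution work is available behind
`osada_normalization=True` but off by default, following the literal
"area as the sample" definition.  C1, "curvature of the circle through
three points", is implemented as the inverse circumradius
4·area/(|pq||qr||rp|) — the most literal reading of that phrase.

Histograms use fixed, mesh-independent domains so bin i means the same
thing for every flower: D1 [0, 1] and D2 [0, 2] (bounded by the unit
enclosing radius), A3 [0, π], D3 [0, √3] and D4 [0, 8/(9√3)]
(generous geometric bounds in the unit ball), and C1 capped at 20
(curvature is unbounded; a unit sphere scores 1, so the cap keeps
typical mass far from the edge).  Out-of-domain values are clipped
into the boundary bins.  Degenerate tuples (collinear triples for
A3/C1, coincident points) are redrawn within their layer, up to 100
rounds, keeping the tuple count exact.

## Flower scalars

S7 (sharpness) is max/min of the vertex-to-centroid distances on the
raw mesh (the ratio is scale-invariant, so normalization is not
needed).  A vertex exactly at the centroid would make it infinite; that
pathological case returns an `inf` sentinel with a warning instead of
raising, so batch extraction over imperfect scans survives.

P8 (contour) is mesh volume over the volume of the minimum enclosing
sphere of the vertices.  The volume is the magnitude of the signed
tetrahedra sum taken **about the vertex centroid**: identical to the
enclosed volume for closed, consistently oriented meshes, and for open
scans a rigid-motion-invariant cone-volume proxy (about the raw origin
the proxy would change under translation).  Open meshes log a
watertightness warning but still return a value.  The minimum
enclosing sphere is exact (randomized incremental algorithm on the
convex-hull vertices, deterministic per seed, least-norm circumsphere
solver for degenerate supports); a fast Ritter approximation is
available via `method="ritter"`.

## Color features

Color works directly in RGB (0–255), matching how scan colors are
acquired; perceptual spaces are out of scope.  50 sampled surface
colors are screened against leaf green (191, 212, 143): points with
Euclidean RGB distance strictly below the threshold N are discarded as
leaf contamination, unless *all* points fall below N, in which case the
flower itself is green (C9 = 6).  The retained points vote: C9 is the
reference color (of eight) with the minimum mean RGB distance, ties
toward the lower index.

N has no published value.  The default is **55**: the tightest gap
between two reference colors is white–green at √(13² + 7² + 57²) ≈
58.9, so any N below that keeps every reference classifiable while
still absorbing green jitter many standard deviations wide (a value of
60 would silently swallow pure white flowers into the green path).

Cp, the color-proportion feature, is only *named* in the source
material; here it is defined as the fraction of retained sample points
whose individually nearest reference equals C9 — a purity measure in
(0, 1] that separates saturated single-color blooms from mixtures.
Both the mean-distance vote and Cp are computed on retained points
only.

## Feature fusion and importance

The fused descriptor is (D1, D2, D3, A3, D4, C1, S7, P8, C9, Cp).  For
the forest, histograms contribute their bins as columns, S7/P8/Cp raw
scalar columns, and C9 an 8-way one-hot block (2411 columns at the
default 400 bins).

Importance is grouped out-of-bag permutation importance: a bagged
ensemble of decision trees (bootstrap rows, √p feature subsampling per
split — i.e. a random forest expressed through `BaggingClassifier`,
which exposes the per-tree bootstrap samples the per-tree OOB error
needs) is fitted; for each tree, the error on its OOB rows is compared
with the error after jointly permuting one *group's* columns, and the
importance of group j is the mean over trees of (permuted − baseline).
Permuting the group jointly — not bin by bin — is what makes the
ranking land on the ten named features rather than 2400 correlated
bins.  Default 500 trees; reproducible per seed.

Rank weights: the ten-feature exponential scheme is the fixed decay
(0.28, 0.19, 0.14, 0.11, 0.08, 0.07, 0.05, 0.04, 0.02, 0.02), summing
to 1; for other feature counts (e.g. the 9-feature shape+color variant
or the 8-feature color-ablated one) a geometric sequence with ratio
0.72 — the least-squares fit to those ten values — is renormalized.
The uniform alternative assigns 1/n (0.1 for ten features).

## Distance, similarity, evaluation

The descriptor distance applies the chi-square form per feature and
combines with the rank weights — the only reading under which the
printed per-feature weights are operative.  Scalars (S7, P8, Cp) are
min-max scaled over the reference collection before entering the
one-component chi-square (raw unbounded scalars would dominate), with
the bounds stored in the index for query-time reuse; without a
collection, fixed natural bounds are used (P8, Cp in [0, 1]; S7 clipped
at 20).  C9 enters through its one-hot indicator: chi-square 2 when the
colors differ.  The result is a pseudometric — non-negative, symmetric,
zero on identical descriptors; the triangle inequality is *not*
guaranteed and nothing relies on it.

Similarity normalizes distances per query over the current collection;
an index-global mode is not needed for the shipped workflows.
Classification is weighted k-NN (default k = 1; vote ties go to the
class with the smaller mean distance).  Retrieval returns the top
k = 6 by default.  Evaluation uses repeated stratified 70/30 splits
(10 seeded repetitions, mean over per-class accuracies) and an
11-point interpolated precision–recall curve averaged over leave-one-
out queries (relevance = same class; singleton classes excluded with a
warning).  The hold-out protocol is this package's own choice; the
source experiments do not state one.

## Synthetic flowers

The generator emulates the *structure* of colored flower scans, not
botany: a radially deformed sphere whose angular lobes play petals, a
small interior icosphere as the stamen, an openness control that
removes a polar cap and flattens the head (strictly decreasing P8), a
damage control that spikes random vertices (strictly increasing S7), a
fullness control scaling the vertical axis, reference colors with
Gaussian jitter (σ = 12 by default, far inside the green-rejection
margin of every non-green reference), and optional leaf-green vertex
contamination.  Collections jitter class-base parameters per sample
(σ = 0.05 in parameter units by default) — with jitter → 0 and fixed
seeds, within-class descriptor distances collapse toward zero, so
separability is controllable.

What passing tests on these meshes shows: the pipeline's measurement
chain (sampling, histograms, scalars, color vote, weighting, distance)
behaves as specified, and the qualitative orderings — color features
helping, exponential weighting matching or beating uniform when
classes share color — reproduce.  What it does *not* show: performance
on real scans, whose noise (holes, registration ghosts, illumination
gradients, inter-penetrating petals) the generator does not model.
Published headline accuracies on proprietary scan collections are
therefore reproduced only directionally, not numerically.

The ten-class benchmark (`benchmark_specs`) pairs the eight reference
colors with distinct shapes and adds two fine-shape twins (same color
and petal count as classes 0/1, differing only in openness resp.
fullness).  At 10 classes × 30 samples, 4000 tuples and 400 bins, the
suite measures mean 1-NN accuracy 1.00 (exponential and uniform) vs
0.95 color-ablated, and PR AUC ≈ 0.99 vs 0.82 — sizes chosen to keep
the full suite under a minute of extraction work on one CPU.

## Numerical choices and limitations

* Histogram frequencies sum to 1 within 1e-12; chi-square terms with a
  zero denominator contribute 0.
* The Welzl sphere uses tolerance 1e-12 for containment; recursion is
  bounded by first reducing to convex-hull vertices.
* Determinism: every stochastic step (sampling, tuples, color
  subsample, forest, splits) derives from an explicit integer seed;
  identical mesh + seed yields byte-identical descriptor JSON.
* Face-color meshes, texture atlases, mesh repair and registration are
  out of scope; color classification assumes the scan's color balance
  roughly matches the reference table.
* S7 uses all vertices — a dense stamen can dominate the minimum; no
  interior-point exclusion is attempted.
* P8 on open meshes is a proxy, monotone in openness for the synthetic
  family but not a physical volume ratio.
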
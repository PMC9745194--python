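"""Shape-distribution functions and their normalized histograms.

A shape distribution summarizes a 3D model by the histogram of a simple
geometric measure evaluated on many random surface-point tuples.  Six
measures are used here:

========  ====================================================  ======
function  measure                                               points
========  ====================================================  ======
D1        distance from a surface point to the centroid          1
D2        distance between two surface points                    2
D3        area of the triangle spanned by three points           3
A3        angle at the middle point of a three-point tuple       3
D4        volume of the tetrahedron spanned by four points       4
C1        curvature (inverse circumradius) of the circle
          through three points                                   3
========  ====================================================  ======

All measures are evaluated on the normalized mesh (unit enclosing
radius), which together with fixed histogram domains makes descriptors
of different models directly comparable and invariant to placement,
orientation and size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import NormalizedMesh
from .sampling import SampleSet, redraw_tuples, sample_surface, stratified_tuples

__all__ = [
    "FUNCTION_IDS",
    "TUPLE_SIZES",
    "DOMAIN_MAX",
    "ShapeHistogram",
    "d1",
    "d2",
    "d3",
    "a3",
    "d4",
    "c1",
    "build_histogram",
    "shape_descriptor",
]

FUNCTION_IDS = ("D1", "D2", "D3", "A3", "D4", "C1")

#: Number of random surface points per tuple (D1 pairs the point with the
#: centroid, so only one random point is drawn).
TUPLE_SIZES = {"D1": 1, "D2": 2, "D3": 3, "A3": 3, "D4": 4, "C1": 3}

#: Fixed histogram domains on the unit-ball-normalized mesh.  D1 and D2
#: are bounded by the enclosing radius; A3 by pi.  D3/D4 use generous
#: geometric bounds (values beyond are clipped into the last bin).  C1 is
#: unbounded, so it is capped: a unit sphere's curvature of 1 sits well
#: inside the default cap of 20.
DOMAIN_MAX = {
    "D1": 1.0,
    "D2": 2.0,
    "D3": float(np.sqrt(3.0)),
    "A3": float(np.pi),
    "D4": 8.0 / (9.0 * np.sqrt(3.0)),
    "C1": 20.0,
}

_DEGENERATE_EPS = 1e-12


def d1(p, center=(0.0, 0.0, 0.0)):
    """Distance from point(s) ``p`` to the centroid."""
    return np.linalg.norm(np.atleast_2d(p) - np.asarray(center, float), axis=-1)


def d2(p, q):
    """Pairwise Euclidean distance."""
    return np.linalg.norm(np.atleast_2d(q) - np.atleast_2d(p), axis=-1)


def d3(p, q, r):
    """Area of the triangle pqr."""
    p, q, r = np.atleast_2d(p), np.atleast_2d(q), np.atleast_2d(r)
    return 0.5 * np.linalg.norm(np.cross(q - p, r - p), axis=-1)


def a3(p, q, r):
    """Angle at vertex ``q`` between rays q->p and q->r, in [0, pi].

    Zero-length rays yield NaN, signalling the caller to resample.
    """
    p, q, r = np.atleast_2d(p), np.atleast_2d(q), np.atleast_2d(r)
    u, v = p - q, r - q
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    denom = nu * nv
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.where(
            denom > _DEGENERATE_EPS,
            np.einsum("...i,...i->...", u, v) / np.where(denom > 0, denom, 1.0),
            np.nan,
        )
    return np.arccos(np.clip(cosang, -1.0, 1.0))


def d4(p, q, r, s):
    """Volume of the tetrahedron pqrs."""
    p, q, r, s = (np.atleast_2d(x) for x in (p, q, r, s))
    return (
        np.abs(np.einsum("...i,...i->...", q - p, np.cross(r - p, s - p))) / 6.0
    )


def c1(p, q, r):
    """Curvature 1/R of the circumcircle of triangle pqr.

    R = |pq| |qr| |rp| / (4 * area); collinear triples yield NaN,
    signalling the caller to resample.
    """
    p, q, r = np.atleast_2d(p), np.atleast_2d(q), np.atleast_2d(r)
    area = d3(p, q, r)
    abc = d2(p, q) * d2(q, r) * d2(r, p)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(
            (area > _DEGENERATE_EPS) & (abc > _DEGENERATE_EPS),
            4.0 * area / np.where(abc > 0, abc, 1.0),
            np.nan,
        )


@dataclass
class ShapeHistogram:
    """A normalized equal-width histogram of one shape-distribution measure."""

    function_id: str
    bin_edges: np.ndarray
    frequencies: np.ndarray
    n_samples: int
    domain_max: float

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if len(self.frequencies) != len(self.bin_edges) - 1:
            raise ValueError("bin_edges must have one more entry than frequencies")

    @property
    def n_bins(self) -> int:
        return len(self.frequencies)

    def to_dict(self) -> dict:
        return {
            "function_id": self.function_id,
            "bins": self.n_bins,
            "domain_max": self.domain_max,
            "n_samples": self.n_samples,
            "frequencies": self.frequencies.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ShapeHistogram":
        edges = np.linspace(0.0, d["domain_max"], d["bins"] + 1)
        return cls(d["function_id"], edges, np.asarray(d["frequencies"]),
                   d["n_samples"], d["domain_max"])


def build_histogram(
    values: np.ndarray,
    function_id: str,
    bins: int = 400,
    domain_max: float | None = None,
) -> ShapeHistogram:
    """Equal-width histogram on [0, domain_max], frequencies summing to 1.

    Values above the domain are clipped into the last bin, negative
    values into the first; this keeps histograms of different meshes on
    an identical support.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("cannot histogram an empty value set")
    if bins < 1:
        raise ValueError("bins must be >= 1")
    if domain_max is None:
        domain_max = DOMAIN_MAX[function_id]
    if domain_max <= 0:
        raise ValueError("domain_max must be positive")
    edges = np.linspace(0.0, float(domain_max), bins + 1)
    counts, _ = np.histogram(np.clip(values, 0.0, domain_max), bins=edges)
    return ShapeHistogram(
        function_id=function_id,
        bin_edges=edges,
        frequencies=counts / counts.sum(),
        n_samples=int(values.size),
        domain_max=float(domain_max),
    )


def _evaluate_function(fid: str, pts: np.ndarray) -> np.ndarray:
    if fid == "D1":
        return d1(pts[:, 0])
    if fid == "D2":
        return d2(pts[:, 0], pts[:, 1])
    if fid == "D3":
        return d3(pts[:, 0], pts[:, 1], pts[:, 2])
    if fid == "A3":
        return a3(pts[:, 0], pts[:, 1], pts[:, 2])
    if fid == "D4":
        return d4(pts[:, 0], pts[:, 1], pts[:, 2], pts[:, 3])
    if fid == "C1":
        return c1(pts[:, 0], pts[:, 1], pts[:, 2])
    raise ValueError(f"unknown shape function {fid!r}")


def function_values(
    fid: str,
    samples: SampleSet,
    count: int,
    rng: np.random.Generator,
    cross_mode: str = "intra",
    resample_rounds: int = 100,
) -> np.ndarray:
    """``count`` values of one shape function on stratified tuples.

    Degenerate tuples (collinear triples for A3/C1, coincident points)
    are redrawn within their layer up to ``resample_rounds`` times so the
    sample count stays exact.
    """
    k = TUPLE_SIZES[fid]
    idx, tuple_layers = stratified_tuples(samples, k, count, rng, cross_mode)
    vals = _evaluate_function(fid, samples.positions[idx])
    for _ in range(resample_rounds):
        bad = np.flatnonzero(~np.isfinite(vals))
        if len(bad) == 0:
            return vals
        redraw_tuples(samples, idx, tuple_layers, bad, rng)
        vals[bad] = _evaluate_function(fid, samples.positions[idx[bad]])
    raise RuntimeError(
        f"{fid}: could not draw non-degenerate tuples after "
        f"{resample_rounds} resampling rounds"
    )


def shape_descriptor(
    mesh: NormalizedMesh,
    n_samples: int = 4000,
    bins: int = 400,
    seed: int = 0,
    cross_mode: str = "intra",
    osada_normalization: bool = False,
    c1_cap: float = 20.0,
    samples: SampleSet | None = None,
) -> dict[str, ShapeHistogram]:
    """All six shape-distribution histograms of a normalized mesh.

    ``n_samples`` tuples are drawn per function from a shared pool of
    ``n_samples`` stratified surface points.  ``osada_normalization``
    linearizes D3 (square root) and D4 (cube root) as in classical
    shape-distribution work; default off, using raw areas and volumes.
    Deterministic for a fixed seed.
    """
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(len(FUNCTION_IDS) + 1)
    if samples is None:
        samples = sample_surface(mesh, n_samples, np.random.default_rng(child_seeds[0]))
    out: dict[str, ShapeHistogram] = {}
    for fid, child in zip(FUNCTION_IDS, child_seeds[1:]):
        rng = np.random.default_rng(child)
        vals = function_values(fid, samples, n_samples, rng, cross_mode)
        dom = c1_cap if fid == "C1" else DOMAIN_MAX[fid]
        if osada_normalization:
            if fid == "D3":
                vals, dom = np.sqrt(vals), np.sqrt(dom)
            elif fid == "D4":
                vals, dom = np.cbrt(vals), np.cbrt(dom)
        out[fid] = build_histogram(vals, fid, bins, dom)
    return out
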
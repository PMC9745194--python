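"""Weighted chi-square retrieval, nearest-neighbor classification, and
precision-recall evaluation.

The distance between two fused descriptors is a weighted sum of
per-feature chi-square distances

    d(A, B) = sum_f  w_f * chi2(A_f, B_f),

where each histogram contributes the chi-square distance of its 400-bin
frequency vector, the scalars S7, P8 and Cp enter as single components
after min-max scaling over the reference collection, and the categorical
C9 enters through its one-hot indicator (chi-square 2 when the colors
differ, 0 otherwise).  Distances are turned into similarities by the
affine map sim = (max_d - d) / (max_d - min_d) over the collection, so
the best match of a query scores 1 and the worst 0.

The weighted sum is a pseudometric: non-negative, symmetric and zero on
identical descriptors; the triangle inequality is not guaranteed by the
chi-square form and is not relied upon.
"""

from __future__ import annotations

import json
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .fusion import FEATURE_NAMES, FlowerDescriptor, WeightVector

__all__ = [
    "chi2_distance",
    "ScalarScaling",
    "descriptor_distance",
    "pairwise_distances",
    "similarity",
    "RetrievalResult",
    "retrieve",
    "classify_nn",
    "PRCurve",
    "precision_recall",
    "DescriptorIndex",
    "evaluate_classification",
]

_SCALED_FEATURES = ("S7", "P8", "Cp")


def chi2_distance(hist_a: np.ndarray, hist_b: np.ndarray) -> float:
    """Chi-square distance sum_i (a_i - b_i)^2 / (a_i + b_i).

    Components where both entries are zero contribute nothing.
    """
    a = np.asarray(hist_a, dtype=float).ravel()
    b = np.asarray(hist_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("chi-square distance needs non-negative entries")
    denom = a + b
    num = (a - b) ** 2
    mask = denom > 0
    return float(np.sum(num[mask] / denom[mask]))


@dataclass(frozen=True)
class ScalarScaling:
    """Min-max bounds of the scalar features over a reference collection.

    Raw S7 is unbounded, so scalars are mapped to [0, 1] before the
    single-component chi-square; the bounds are stored with the index so
    queries are scaled consistently at retrieval time.
    """

    bounds: dict[str, tuple[float, float]]

    @classmethod
    def from_descriptors(cls, descriptors: list[FlowerDescriptor]) -> "ScalarScaling":
        bounds = {}
        for name in _SCALED_FEATURES:
            vals = np.array(
                [_raw_scalar(d, name) for d in descriptors], dtype=float
            )
            vals = vals[np.isfinite(vals)]
            if len(vals) == 0:
                bounds[name] = (0.0, 1.0)
            else:
                bounds[name] = (float(vals.min()), float(vals.max()))
        return cls(bounds)

    @classmethod
    def natural(cls) -> "ScalarScaling":
        """Fixed fallback bounds for use without a reference collection:
        P8 and Cp already live in [0, 1]; S7 is clipped at 20 (a heavily
        damaged scan; typical blooms sit well below)."""
        return cls({"S7": (1.0, 20.0), "P8": (0.0, 1.0), "Cp": (0.0, 1.0)})

    def scale(self, name: str, value: float) -> float:
        lo, hi = self.bounds[name]
        if hi <= lo:
            return 0.0
        return float(np.clip((value - lo) / (hi - lo), 0.0, 1.0))


def _raw_scalar(d: FlowerDescriptor, name: str) -> float:
    if name == "S7":
        return d.scalars.s7
    if name == "P8":
        return d.scalars.p8
    if name == "Cp":
        return d.color.cp if d.has_color else np.nan
    raise KeyError(name)


def descriptor_distance(
    a: FlowerDescriptor,
    b: FlowerDescriptor,
    weights: WeightVector,
    scaling: ScalarScaling | None = None,
) -> float:
    """Weighted per-feature chi-square distance between two descriptors.

    If either descriptor lacks color, the color terms contribute zero.
    Without an explicit ``scaling`` the natural fixed bounds are used
    (adequate for ad-hoc pairwise use; build a :class:`ScalarScaling`
    from the full collection for retrieval).
    """
    if a.histograms.keys() != b.histograms.keys():
        raise ValueError("descriptors carry different histogram sets")
    if scaling is None:
        scaling = ScalarScaling.natural()
    total = 0.0
    for fid, ha in a.histograms.items():
        hb = b.histograms[fid]
        if ha.n_bins != hb.n_bins:
            raise ValueError(f"{fid}: histogram bin counts differ")
        total += weights.get(fid) * chi2_distance(ha.frequencies, hb.frequencies)
    for name in ("S7", "P8"):
        va = scaling.scale(name, _raw_scalar(a, name))
        vb = scaling.scale(name, _raw_scalar(b, name))
        total += weights.get(name) * chi2_distance([va], [vb])
    if a.has_color and b.has_color:
        total += weights.get("C9") * (2.0 if a.color.c9 != b.color.c9 else 0.0)
        va = scaling.scale("Cp", a.color.cp)
        vb = scaling.scale("Cp", b.color.cp)
        total += weights.get("Cp") * chi2_distance([va], [vb])
    return total


def pairwise_distances(
    descriptors: list[FlowerDescriptor],
    weights: WeightVector,
    scaling: ScalarScaling | None = None,
) -> np.ndarray:
    """Full (n, n) weighted distance matrix, vectorized per feature."""
    n = len(descriptors)
    if n == 0:
        raise ValueError("empty collection")
    if scaling is None:
        scaling = ScalarScaling.from_descriptors(descriptors)
    dist = np.zeros((n, n))
    for fid in descriptors[0].histograms:
        w = weights.get(fid)
        if w == 0.0:
            continue
        H = np.vstack([d.histograms[fid].frequencies for d in descriptors])
        for i in range(n):
            num = (H[i] - H) ** 2
            denom = H[i] + H
            with np.errstate(invalid="ignore", divide="ignore"):
                terms = np.where(denom > 0, num / np.where(denom > 0, denom, 1), 0.0)
            dist[i] += w * terms.sum(axis=1)
    for name in ("S7", "P8"):
        w = weights.get(name)
        if w == 0.0:
            continue
        v = np.array([scaling.scale(name, _raw_scalar(d, name)) for d in descriptors])
        num = (v[:, None] - v[None]) ** 2
        denom = v[:, None] + v[None]
        with np.errstate(invalid="ignore", divide="ignore"):
            dist += w * np.where(denom > 0, num / np.where(denom > 0, denom, 1), 0.0)
    if all(d.has_color for d in descriptors):
        c9 = np.array([d.color.c9 for d in descriptors])
        dist += weights.get("C9") * 2.0 * (c9[:, None] != c9[None])
        v = np.array([scaling.scale("Cp", d.color.cp) for d in descriptors])
        num = (v[:, None] - v[None]) ** 2
        denom = v[:, None] + v[None]
        with np.errstate(invalid="ignore", divide="ignore"):
            dist += weights.get("Cp") * np.where(
                denom > 0, num / np.where(denom > 0, denom, 1), 0.0
            )
    return dist


def similarity(dist: float, max_dis: float, min_dis: float) -> float:
    """Affine similarity (max_d - d) / (max_d - min_d) in [0, 1]."""
    if max_dis <= min_dis:
        raise ValueError("degenerate collection: max distance equals min distance")
    if dist < min_dis or dist > max_dis:
        warnings.warn("distance outside [min_dis, max_dis]; clipping", stacklevel=2)
        dist = float(np.clip(dist, min_dis, max_dis))
    return (max_dis - dist) / (max_dis - min_dis)


@dataclass
class RetrievalResult:
    """Ranked neighbors of one query with distances and similarities."""

    query_id: str
    entries: list[tuple[str, float, float]]  # (target id, distance, similarity)
    weights: WeightVector

    @property
    def target_ids(self) -> list[str]:
        return [e[0] for e in self.entries]


def retrieve(
    query: FlowerDescriptor,
    collection: list[FlowerDescriptor],
    weights: WeightVector,
    k: int = 6,
    ids: list[str] | None = None,
    scaling: ScalarScaling | None = None,
    query_id: str = "query",
) -> RetrievalResult:
    """Top-k most similar collection members (ascending distance).

    Similarities are normalized by the query's distance range over the
    *whole* collection; ties keep collection order; ``k`` larger than
    the collection returns everything.
    """
    if not collection:
        raise ValueError("empty collection")
    if k <= 0:
        raise ValueError("k must be positive")
    if ids is None:
        ids = [str(i) for i in range(len(collection))]
    if scaling is None:
        scaling = ScalarScaling.from_descriptors(collection)
    d = np.array(
        [descriptor_distance(query, t, weights, scaling) for t in collection]
    )
    dmin, dmax = float(d.min()), float(d.max())
    order = np.argsort(d, kind="stable")[: min(k, len(collection))]
    if dmax > dmin:
        sims = (dmax - d) / (dmax - dmin)
    else:
        sims = np.ones_like(d)
    entries = [(ids[i], float(d[i]), float(sims[i])) for i in order]
    return RetrievalResult(query_id=query_id, entries=entries, weights=weights)


def classify_nn(
    query: FlowerDescriptor,
    training: list[FlowerDescriptor],
    labels: list,
    weights: WeightVector,
    k: int = 1,
    scaling: ScalarScaling | None = None,
):
    """k-nearest-neighbor majority vote; vote ties go to the class with
    the smallest mean distance among the k neighbors."""
    if not training:
        raise ValueError("empty training set")
    if scaling is None:
        scaling = ScalarScaling.from_descriptors(training)
    d = np.array(
        [descriptor_distance(query, t, weights, scaling) for t in training]
    )
    return _vote(d, np.asarray(labels, dtype=object), k)


def _vote(distances: np.ndarray, labels: np.ndarray, k: int):
    order = np.argsort(distances, kind="stable")[: min(k, len(distances))]
    near = labels[order]
    counts = Counter(near)
    top = max(counts.values())
    tied = [c for c, v in counts.items() if v == top]
    if len(tied) == 1:
        return tied[0]
    means = {c: distances[order][near == c].mean() for c in tied}
    return min(means, key=means.get)


@dataclass
class PRCurve:
    """Interpolated precision-recall curve on an 11-point recall grid."""

    recall: np.ndarray
    precision: np.ndarray

    def auc(self) -> float:
        return float(np.trapezoid(self.precision, self.recall))


def precision_recall(
    ranked_labels: list[np.ndarray],
    query_labels: list,
    grid: np.ndarray | None = None,
) -> PRCurve:
    """Average interpolated PR curve over queries.

    ``ranked_labels[i]`` lists the class labels of query i's ranked
    results (the query itself excluded); relevance means sharing the
    query's class.  Queries whose class has no other member are skipped
    with a warning.  Interpolated precision at recall r is the maximum
    precision achieved at any recall >= r, evaluated on the grid
    {0, 0.1, ..., 1}.
    """
    if grid is None:
        grid = np.linspace(0.0, 1.0, 11)
    curves = []
    for ranked, qlab in zip(ranked_labels, query_labels):
        rel = np.asarray([lab == qlab for lab in ranked], dtype=float)
        n_rel = rel.sum()
        if n_rel == 0:
            warnings.warn(
                f"query of singleton class {qlab!r} excluded from PR curve",
                stacklevel=2,
            )
            continue
        tp = np.cumsum(rel)
        prec = tp / np.arange(1, len(rel) + 1)
        rec = tp / n_rel
        interp = np.array([prec[rec >= r].max() if np.any(rec >= r) else 0.0
                           for r in grid])
        curves.append(interp)
    if not curves:
        raise ValueError("no evaluable queries (all classes singletons)")
    return PRCurve(recall=grid.copy(), precision=np.mean(curves, axis=0))


# ---------------------------------------------------------------------------
# Index and evaluation helpers
# ---------------------------------------------------------------------------


@dataclass
class DescriptorIndex:
    """A searchable collection: descriptors, labels/ids, scalar bounds."""

    descriptors: list[FlowerDescriptor]
    ids: list[str]
    labels: list[str] | None = None
    scaling: ScalarScaling = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.scaling is None:
            self.scaling = ScalarScaling.from_descriptors(self.descriptors)

    def retrieve(self, query, weights, k=6, query_id="query") -> RetrievalResult:
        return retrieve(
            query, self.descriptors, weights, k=k, ids=self.ids,
            scaling=self.scaling, query_id=query_id,
        )

    def classify(self, query, weights, k=1):
        if self.labels is None:
            raise ValueError("index has no labels")
        return classify_nn(
            query, self.descriptors, self.labels, weights, k=k, scaling=self.scaling
        )

    def save(self, path: str | Path) -> None:
        """JSON-lines: one header record, then one record per descriptor."""
        with open(path, "w") as fh:
            fh.write(json.dumps({"scaling": self.scaling.bounds}) + "\n")
            for i, d in enumerate(self.descriptors):
                rec = {
                    "id": self.ids[i],
                    "label": None if self.labels is None else self.labels[i],
                    "descriptor": d.to_dict(),
                }
                fh.write(json.dumps(rec, sort_keys=True) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "DescriptorIndex":
        with open(path) as fh:
            header = json.loads(fh.readline())
            descriptors, ids, labels = [], [], []
            for line in fh:
                rec = json.loads(line)
                ids.append(rec["id"])
                labels.append(rec["label"])
                descriptors.append(FlowerDescriptor.from_dict(rec["descriptor"]))
        if all(lab is None for lab in labels):
            labels = None
        scaling = ScalarScaling(
            {k: tuple(v) for k, v in header["scaling"].items()}
        )
        return cls(descriptors=descriptors, ids=ids, labels=labels, scaling=scaling)


def evaluate_classification(
    descriptors: list[FlowerDescriptor],
    labels: list,
    weights: WeightVector,
    k: int = 1,
    test_fraction: float = 0.3,
    n_repeats: int = 10,
    seed: int = 0,
    dist: np.ndarray | None = None,
) -> dict:
    """Repeated stratified hold-out accuracy of the weighted k-NN.

    Returns per-class accuracies and the mean over classes, averaged
    over ``n_repeats`` seeded stratified 70/30 splits.  A precomputed
    distance matrix may be passed to avoid re-deriving it per variant.
    """
    from sklearn.model_selection import StratifiedShuffleSplit

    y = np.asarray(labels, dtype=object)
    if dist is None:
        dist = pairwise_distances(descriptors, weights)
    splitter = StratifiedShuffleSplit(
        n_splits=n_repeats, test_size=test_fraction, random_state=seed
    )
    classes = np.unique(y.astype(str))
    correct = {c: 0 for c in classes}
    total = {c: 0 for c in classes}
    for train_idx, test_idx in splitter.split(np.zeros(len(y)), y.astype(str)):
        for i in test_idx:
            pred = _vote(dist[i, train_idx], y[train_idx], k)
            c = str(y[i])
            total[c] += 1
            correct[c] += int(pred == y[i])
    per_class = {c: correct[c] / total[c] for c in classes if total[c]}
    return {
        "per_class": per_class,
        "mean": float(np.mean(list(per_class.values()))),
    }
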
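"""Fused flower descriptor, feature importance, and rank weights.

The fused descriptor combines ten features: the six shape-distribution
histograms (D1, D2, D3, A3, D4, C1), the sharpness and contour scalars
(S7, P8), the categorical color indicator C9 and the color-purity
fraction Cp.

Feature weighting is driven by out-of-bag (OOB) permutation importance
of a random forest: for each named feature *group* (all 400 bins of one
histogram move together), the group's columns are permuted jointly
across each tree's OOB rows and the mean rise in OOB error over trees is
that feature's importance.  Features ranked by importance then receive
exponentially decaying weights; with ten features the canonical decay is
(0.28, 0.19, 0.14, 0.11, 0.08, 0.07, 0.05, 0.04, 0.02, 0.02).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import BaggingClassifier
from sklearn.tree import DecisionTreeClassifier

from .color import ColorFeature, classify_color
from .config import RunConfig
from .distributions import FUNCTION_IDS, ShapeHistogram, shape_descriptor
from .errors import FeatureUnavailableError
from .features import FlowerScalars, contour, sharpness
from .mesh import TriangleMesh, normalize_mesh
from .sampling import sample_surface

__all__ = [
    "FEATURE_NAMES",
    "EXPONENTIAL_WEIGHTS_10",
    "FlowerDescriptor",
    "WeightVector",
    "ImportanceReport",
    "extract_descriptor",
    "feature_matrix",
    "rf_oob_importance",
    "exponential_weights",
    "uniform_weights",
]

#: Canonical feature order used for matrices and weight vectors.
FEATURE_NAMES = ("D1", "D2", "D3", "A3", "D4", "C1", "S7", "P8", "C9", "Cp")

#: Exponential rank weights for a ten-feature ranking, highest rank first.
EXPONENTIAL_WEIGHTS_10 = (0.28, 0.19, 0.14, 0.11, 0.08, 0.07, 0.05, 0.04, 0.02, 0.02)

#: Decay ratio for rankings of other lengths (least-squares fit of a
#: geometric sequence to the ten canonical weights).
GEOMETRIC_DECAY = 0.72


@dataclass
class FlowerDescriptor:
    """The fused per-flower feature object."""

    histograms: dict[str, ShapeHistogram]
    scalars: FlowerScalars
    color: ColorFeature | None
    meta: dict = field(default_factory=dict)

    @property
    def has_color(self) -> bool:
        return self.color is not None

    def to_dict(self) -> dict:
        return {
            "histograms": {fid: h.to_dict() for fid, h in self.histograms.items()},
            "S7": self.scalars.s7,
            "P8": self.scalars.p8,
            "color": None if self.color is None else self.color.to_dict(),
            "meta": self.meta,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "FlowerDescriptor":
        color = d.get("color")
        return cls(
            histograms={
                fid: ShapeHistogram.from_dict(h) for fid, h in d["histograms"].items()
            },
            scalars=FlowerScalars(s7=d["S7"], p8=d["P8"]),
            color=None
            if color is None
            else ColorFeature(
                c9=color["C9"],
                cp=color["Cp"],
                n_retained=color["n_retained"],
                threshold_n=color["threshold_n"],
            ),
            meta=d.get("meta", {}),
        )

    @classmethod
    def from_json(cls, s: str) -> "FlowerDescriptor":
        return cls.from_dict(json.loads(s))


def extract_descriptor(
    mesh: TriangleMesh,
    config: RunConfig | None = None,
    mesh_path: str | None = None,
) -> FlowerDescriptor:
    """Full descriptor pipeline: normalize, sample, six histograms,
    sharpness, contour, and (unless shape-only) color classification.

    Deterministic for a fixed ``config.seed``.
    """
    cfg = config or RunConfig()
    mesh.validate_for_descriptors()
    nmesh = normalize_mesh(mesh)
    ss = np.random.SeedSequence(cfg.seed)
    sample_child, color_child = ss.spawn(7)[0], np.random.SeedSequence([cfg.seed, 1])
    samples = sample_surface(nmesh, cfg.n_samples, np.random.default_rng(sample_child))
    hists = shape_descriptor(
        nmesh,
        n_samples=cfg.n_samples,
        bins=cfg.bins,
        seed=cfg.seed,
        cross_mode=cfg.cross_mode,
        osada_normalization=cfg.osada_normalization,
        c1_cap=cfg.c1_cap,
        samples=samples,
    )
    scalars = FlowerScalars(s7=sharpness(mesh), p8=contour(mesh))
    color = None
    if not cfg.shape_only and mesh.has_colors:
        color = classify_color(
            samples.colors,
            n_points=cfg.n_color_points,
            threshold_n=cfg.green_threshold,
            seed=np.random.default_rng(color_child),
        )
    meta = {
        "seed": cfg.seed,
        "n_samples": cfg.n_samples,
        "bins": cfg.bins,
        "cross_mode": cfg.cross_mode,
        "mesh_path": mesh_path,
    }
    return FlowerDescriptor(histograms=hists, scalars=scalars, color=color, meta=meta)


# ---------------------------------------------------------------------------
# Feature matrix and grouped OOB permutation importance
# ---------------------------------------------------------------------------


def feature_matrix(
    descriptors: list[FlowerDescriptor],
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Flatten descriptors into a design matrix with a column map.

    Histogram bins become individual columns, S7/P8/Cp raw scalar
    columns, and C9 an 8-way one-hot block.  The column map records the
    column indices of each named feature group so importance permutation
    can move whole groups jointly.  Color columns are included only when
    every descriptor carries color.
    """
    if not descriptors:
        raise ValueError("feature_matrix needs at least one descriptor")
    bins = descriptors[0].histograms["D1"].n_bins
    for d in descriptors:
        if any(d.histograms[f].n_bins != bins for f in FUNCTION_IDS):
            raise ValueError("descriptors have heterogeneous histogram configs")
    with_color = all(d.has_color for d in descriptors)
    if not with_color and any(d.has_color for d in descriptors):
        raise ValueError("mixed color/shape-only descriptors")
    cols: list[np.ndarray] = []
    column_map: dict[str, np.ndarray] = {}
    cursor = 0

    def add(name: str, block: np.ndarray) -> None:
        nonlocal cursor
        block = np.atleast_2d(block.T).T if block.ndim == 1 else block
        cols.append(block)
        column_map[name] = np.arange(cursor, cursor + block.shape[1])
        cursor += block.shape[1]

    for fid in FUNCTION_IDS:
        add(fid, np.vstack([d.histograms[fid].frequencies for d in descriptors]))
    add("S7", np.array([[d.scalars.s7] for d in descriptors]))
    add("P8", np.array([[d.scalars.p8] for d in descriptors]))
    if with_color:
        onehot = np.zeros((len(descriptors), 8))
        for i, d in enumerate(descriptors):
            onehot[i, d.color.c9 - 1] = 1.0
        add("C9", onehot)
        add("Cp", np.array([[d.color.cp] for d in descriptors]))
    return np.hstack(cols), column_map


@dataclass
class ImportanceReport:
    """Grouped OOB permutation importances and the implied ranking."""

    importances: dict[str, float]
    ranks: dict[str, int]
    n_trees: int
    seed: int

    @property
    def ranking(self) -> list[str]:
        return sorted(self.ranks, key=self.ranks.get)

    def to_json(self) -> str:
        return json.dumps(
            {
                "importances": self.importances,
                "ranks": self.ranks,
                "n_trees": self.n_trees,
                "seed": self.seed,
            },
            sort_keys=True,
        )


def rf_oob_importance(
    matrix: np.ndarray,
    labels: np.ndarray,
    groups: dict[str, np.ndarray],
    n_trees: int = 500,
    seed: int = 0,
    max_depth: int | None = None,
) -> ImportanceReport:
    """Grouped out-of-bag permutation importance of a random forest.

    A bagged ensemble of ``n_trees`` decision trees (sqrt feature
    subsampling at each split, bootstrap rows) is fitted; for each tree
    the baseline error on its OOB rows is compared with the error after
    jointly permuting one group's columns across those rows.  The
    importance of group j is the mean over trees of (permuted error -
    baseline error); larger means more important.  Ranks are descending
    by importance (1 = most important).
    """
    X = np.asarray(matrix, dtype=float)
    y = np.asarray(labels)
    classes, y_enc = np.unique(y, return_inverse=True)
    if len(classes) < 2:
        raise ValueError("importance needs at least two classes")
    forest = BaggingClassifier(
        estimator=DecisionTreeClassifier(max_features="sqrt", max_depth=max_depth),
        n_estimators=n_trees,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X, y_enc)
    rng = np.random.default_rng(seed)
    n = len(X)
    sums = {g: 0.0 for g in groups}
    for tree, sampled in zip(forest.estimators_, forest.estimators_samples_):
        oob = np.setdiff1d(np.arange(n), sampled, assume_unique=False)
        if len(oob) == 0:
            continue
        Xo = X[oob]
        yo = y_enc[oob]
        e_base = float(np.mean(tree.predict(Xo) != yo))
        for gname, gcols in groups.items():
            perm = rng.permutation(len(oob))
            Xp = Xo.copy()
            Xp[:, gcols] = Xo[perm][:, gcols]
            e_perm = float(np.mean(tree.predict(Xp) != yo))
            sums[gname] += e_perm - e_base
    importances = {g: s / n_trees for g, s in sums.items()}
    order = sorted(importances, key=lambda g: -importances[g])
    ranks = {g: i + 1 for i, g in enumerate(order)}
    return ImportanceReport(
        importances=importances, ranks=ranks, n_trees=n_trees, seed=seed
    )


# ---------------------------------------------------------------------------
# Rank-based weights
# ---------------------------------------------------------------------------


@dataclass
class WeightVector:
    """Non-negative per-feature weights summing to 1 (order preserved)."""

    weights: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.weights.values())
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"weights must sum to 1, got {total}")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("weights must be non-negative")

    def __getitem__(self, name: str) -> float:
        return self.weights[name]

    def get(self, name: str, default: float = 0.0) -> float:
        return self.weights.get(name, default)

    def items(self):
        return self.weights.items()

    def drop(self, names: tuple[str, ...]) -> "WeightVector":
        """Zero the given features and renormalize (feature ablation)."""
        kept = {k: v for k, v in self.weights.items() if k not in names}
        total = sum(kept.values())
        if total <= 0:
            raise ValueError("cannot drop every weighted feature")
        return WeightVector({k: v / total for k, v in kept.items()})

    def to_json(self) -> str:
        return json.dumps(self.weights)


def exponential_weights(ranking: list[str]) -> WeightVector:
    """Exponentially decaying weights by importance rank.

    A ten-feature ranking receives the canonical decay
    (0.28, 0.19, 0.14, 0.11, 0.08, 0.07, 0.05, 0.04, 0.02, 0.02);
    other lengths use a renormalized geometric sequence with ratio 0.72.
    """
    if len(set(ranking)) != len(ranking):
        raise ValueError("duplicate feature names in ranking")
    if len(ranking) == 10:
        values = EXPONENTIAL_WEIGHTS_10
    else:
        raw = GEOMETRIC_DECAY ** np.arange(len(ranking))
        values = tuple(raw / raw.sum())
    return WeightVector({name: float(w) for name, w in zip(ranking, values)})


def uniform_weights(names: list[str] = list(FEATURE_NAMES)) -> WeightVector:
    """Equal weights (0.1 per feature for the ten-feature descriptor)."""
    if len(set(names)) != len(names):
        raise ValueError("duplicate feature names")
    w = 1.0 / len(names)
    return WeightVector({name: w for name in names})
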
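"""Color features: green-leaf rejection and reference-color classification.

Flower color is read directly in RGB space.  Sampled surface colors are
first screened against a reference leaf green — points closer than a
threshold ``N`` (Euclidean RGB distance) are treated as leaf
contamination and dropped, unless *every* point is green, in which case
the flower itself is green.  The retained points are then matched
against eight reference flower colors; the reference with the smallest
mean RGB distance gives the categorical color indicator C9 (1..8), and
the fraction of retained points individually nearest to that reference
gives the color-purity feature Cp.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import FeatureUnavailableError

__all__ = [
    "REFERENCE_GREEN",
    "DEFAULT_GREEN_THRESHOLD",
    "ColorReferenceTable",
    "ColorFeature",
    "delta_e",
    "reject_green",
    "classify_color",
]

#: RGB of the leaf green used for contamination rejection (also the
#: reference color of green flowers, index 6).
REFERENCE_GREEN = (191, 212, 143)

#: Default rejection threshold N.  The value is chosen so that no two
#: reference colors eliminate each other: the closest pair (green vs.
#: white) sits at an RGB distance of ~58.9, so 55 keeps white flowers
#: alive while still absorbing leaf-green jitter many sigma wide.
DEFAULT_GREEN_THRESHOLD = 55.0

_DEFAULT_ENTRIES = (
    (1, "red", (217, 32, 37)),
    (2, "yellow", (255, 210, 3)),
    (3, "pink", (245, 163, 199)),
    (4, "black-and-red", (74, 3, 19)),
    (5, "blue", (49, 130, 237)),
    (6, "green", REFERENCE_GREEN),
    (7, "white", (204, 205, 200)),
    (8, "orange", (254, 171, 5)),
)


@dataclass(frozen=True)
class ColorReferenceTable:
    """Ordered reference colors: (index, name, RGB)."""

    entries: tuple = _DEFAULT_ENTRIES

    def __post_init__(self) -> None:
        indices = [e[0] for e in self.entries]
        if len(set(indices)) != len(indices):
            raise ValueError("duplicate color indices in reference table")
        for _, _, rgb in self.entries:
            if any(not (0 <= v <= 255) for v in rgb):
                raise ValueError(f"RGB out of range in reference table: {rgb}")

    @property
    def indices(self) -> np.ndarray:
        return np.array([e[0] for e in self.entries])

    @property
    def rgb_matrix(self) -> np.ndarray:
        return np.array([e[2] for e in self.entries], dtype=float)

    def name_of(self, index: int) -> str:
        for idx, name, _ in self.entries:
            if idx == index:
                return name
        raise KeyError(index)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ColorReferenceTable":
        """Load ``index,name,r,g,b`` rows (header optional)."""
        entries = []
        with open(path, newline="") as fh:
            for row in csv.reader(fh):
                if not row or row[0].lstrip().startswith("#") or row[0] == "index":
                    continue
                entries.append(
                    (int(row[0]), row[1], (int(row[2]), int(row[3]), int(row[4])))
                )
        return cls(tuple(entries))


@dataclass(frozen=True)
class ColorFeature:
    """Categorical color indicator C9 plus the purity feature Cp."""

    c9: int
    cp: float
    n_retained: int
    threshold_n: float

    def to_dict(self) -> dict:
        return {
            "C9": self.c9,
            "Cp": self.cp,
            "n_retained": self.n_retained,
            "threshold_n": self.threshold_n,
        }


def delta_e(a, b) -> np.ndarray | float:
    """Euclidean RGB distance; broadcasts over arrays of colors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(a < 0) or np.any(a > 255) or np.any(b < 0) or np.any(b > 255):
        raise ValueError("RGB components must lie in [0, 255]")
    d = np.linalg.norm(np.atleast_2d(a) - np.atleast_2d(b), axis=-1)
    return float(d[0]) if a.ndim == 1 and b.ndim == 1 else d


def reject_green(
    points: np.ndarray,
    reference_green=REFERENCE_GREEN,
    threshold_n: float = DEFAULT_GREEN_THRESHOLD,
) -> tuple[np.ndarray, bool]:
    """Drop points whose distance to leaf green is strictly below ``N``.

    Returns ``(retained, all_green)``.  When every point is below the
    threshold the flower itself is green (``all_green=True``) and the
    full point set is returned unfiltered.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(points) == 0:
        raise ValueError("reject_green needs at least one point")
    d = delta_e(points, np.asarray(reference_green, dtype=float))
    green = d < threshold_n
    if bool(np.all(green)):
        return points, True
    return points[~green], False


def classify_color(
    colors: np.ndarray,
    table: ColorReferenceTable = ColorReferenceTable(),
    n_points: int = 50,
    threshold_n: float = DEFAULT_GREEN_THRESHOLD,
    seed: int | np.random.Generator = 0,
) -> ColorFeature:
    """Classify a flower's color from sampled surface colors.

    ``n_points`` colors are subsampled (without replacement when
    possible), leaf green is rejected, and the reference color with the
    minimum mean RGB distance over the retained points becomes C9 (ties
    resolved toward the lowest index).  Cp is the fraction of retained
    points whose individually nearest reference equals C9.
    """
    if colors is None:
        raise FeatureUnavailableError("mesh has no vertex colors")
    colors = np.asarray(colors, dtype=float).reshape(-1, 3)
    if len(colors) == 0:
        raise FeatureUnavailableError("no surface colors to classify")
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if len(colors) > n_points:
        colors = colors[rng.choice(len(colors), size=n_points, replace=False)]
    retained, all_green = reject_green(colors, threshold_n=threshold_n)
    indices = table.indices
    if all_green:
        # the flower itself is green: C9 is the reference nearest leaf green
        dref = np.linalg.norm(
            table.rgb_matrix - np.asarray(REFERENCE_GREEN, dtype=float), axis=1
        )
        green_idx = int(indices[int(np.argmin(dref))])
        return ColorFeature(
            c9=green_idx, cp=1.0, n_retained=len(retained), threshold_n=threshold_n
        )
    # (n_retained, n_refs) distance matrix
    dmat = np.linalg.norm(retained[:, None, :] - table.rgb_matrix[None], axis=-1)
    c9 = int(indices[int(np.argmin(dmat.mean(axis=0)))])
    nearest = indices[np.argmin(dmat, axis=1)]
    cp = float(np.mean(nearest == c9))
    return ColorFeature(
        c9=c9, cp=cp, n_retained=len(retained), threshold_n=threshold_n
    )
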
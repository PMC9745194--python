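"""Run configuration for descriptor extraction and evaluation.

Defaults reproduce the reference operating point: 4000 sample tuples per
shape function, 400 histogram bins, three equal-volume sampling layers,
50 color points.  The green-rejection threshold N defaults to 55, just
under the tightest inter-reference color gap (white vs. green, ~58.9),
so no reference color can eliminate another.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path


@dataclass
class RunConfig:
    n_samples: int = 4000          # tuples per shape function
    bins: int = 400                # histogram resolution
    layer_parts: int = 3           # equal-volume shells
    cross_mode: str = "intra"      # tuple layering: intra | inter
    n_color_points: int = 50       # colors sampled for C9/Cp
    green_threshold: float = 55.0  # leaf-green rejection N (RGB distance)
    c1_cap: float = 20.0           # curvature histogram cap
    osada_normalization: bool = False  # sqrt/cbrt linearization of D3/D4
    shape_only: bool = False       # skip color features entirely
    area_weighted_centroid: bool = False
    weight_mode: str = "exponential"   # exponential | uniform | custom
    custom_weights: dict = field(default_factory=dict)
    k: int = 6                     # neighbors returned by retrieval
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        return cls(**known)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
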
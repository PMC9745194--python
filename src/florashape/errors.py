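"""Exception types shared across the package."""


class FloraShapeError(Exception):
    """Base class for all package-specific errors."""


class MeshFormatError(FloraShapeError):
    """A mesh file could not be parsed or violates structural constraints."""


class DegenerateMeshError(FloraShapeError):
    """A mesh is too degenerate for the requested computation
    (all vertices coincident, zero surface area, ...)."""


class FeatureUnavailableError(FloraShapeError):
    """A feature was requested that the input cannot provide
    (e.g. color classification of a colorless mesh)."""
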
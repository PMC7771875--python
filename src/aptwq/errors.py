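"""Exception hierarchy for the APTw quantification pipeline."""


class AptwError(Exception):
    """Base class for all package-specific errors."""


class InvalidReferenceError(AptwError):
    """The unsaturated reference signal S0 is zero or negative."""


class ShapeMismatchError(AptwError):
    """Array shapes disagree (signal/offset lengths, volume grids, ...)."""


class UncorrectableSpectrumError(AptwError):
    """No interior Z-spectrum minimum near 0 ppm; B0 correction impossible."""


class CoverageError(AptwError):
    """The asymmetry integration window falls outside the sampled offsets."""


class PlacementError(AptwError):
    """No admissible ROI placement exists for the requested disc size."""


class SeparationError(AptwError):
    """Logistic regression design is degenerate (complete separation or a
    constant predictor)."""


class PhantomSpecError(AptwError):
    """Invalid digital-phantom specification (overlapping lesions, lesion
    outside the grid, infeasible pool set, ...)."""


class ConfigError(AptwError):
    """Malformed run configuration (unknown keys, missing files)."""
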
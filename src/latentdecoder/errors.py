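"""Exception types shared across the package."""


class ConfigError(ValueError):
    """A configuration field violates its invariant; the message names the field."""


class ShapeError(ValueError):
    """Array dimensions are inconsistent with the model or data contract."""


class DataError(ValueError):
    """Input data contain NaN/Inf or violate a domain constraint."""


class TrainingError(RuntimeError):
    """Optimization diverged (non-finite loss); the message names the epoch."""


class StateError(RuntimeError):
    """An operation was called on a model in the wrong state (e.g. untrained)."""


class RankError(ValueError):
    """A subspace operation received rank-deficient input."""
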
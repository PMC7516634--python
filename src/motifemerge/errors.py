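"""Exception types shared across the package."""


class MotifEmergeError(Exception):
    """Base class for package errors."""


class InvalidConfigurationError(MotifEmergeError, ValueError):
    """A configuration value violates its contract."""


class InvalidSampleError(MotifEmergeError, ValueError):
    """A data sample or subgraph violates the generative model's invariants."""


class DegenerateGeometryError(MotifEmergeError, ValueError):
    """Spatial geometry is degenerate (e.g. coincident nodes)."""


class AnnealingFailure(MotifEmergeError, RuntimeError):
    """Edge annealing could not reach the requested number of groups."""


class DegenerateFitError(MotifEmergeError, ValueError):
    """Distribution fit is degenerate (constant input)."""


class DivergenceError(MotifEmergeError, RuntimeError):
    """Training loss became non-finite."""

    def __init__(self, epoch: int):
        super().__init__(f"non-finite loss at epoch {epoch}")
        self.epoch = epoch


class DimensionError(MotifEmergeError, ValueError):
    """Array shapes are inconsistent with the model architecture."""
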
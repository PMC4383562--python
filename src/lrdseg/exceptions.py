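"""Exception hierarchy for lrdseg."""


class LrdsegError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(LrdsegError, ValueError):
    """A model or kernel parameter is out of its valid range."""


class InvalidInputError(LrdsegError, ValueError):
    """An input array is malformed (non-finite, wrong shape, ...)."""


class InitializationError(LrdsegError, ValueError):
    """A level-set initialization region is degenerate (empty or full)."""


class DegenerateClassError(LrdsegError, RuntimeError):
    """A cluster has (numerically) zero membership mass."""

    def __init__(self, class_index: int, message: str | None = None):
        self.class_index = class_index
        super().__init__(
            message or f"class {class_index} has numerically zero membership mass"
        )


class DegenerateBiasError(LrdsegError, RuntimeError):
    """The bias-update denominator vanished somewhere in the domain."""


class DegeneratePartitionError(LrdsegError, RuntimeError):
    """The difference-update denominator vanished (memberships not a partition)."""


class DivergenceError(LrdsegError, RuntimeError):
    """The level-set evolution produced non-finite values."""


class UndefinedMetricError(LrdsegError, ValueError):
    """An overlap metric is undefined (empty mask, absent class)."""
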
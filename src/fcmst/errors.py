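"""Exception types shared across the pipeline stages."""


class FCMSTError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(FCMSTError, ValueError):
    """A simulation or configuration spec violates one of its invariants."""


class InvalidParameterError(FCMSTError, ValueError):
    """A processing parameter (band edge, filter order, ...) is infeasible."""


class EpochShortageError(FCMSTError, RuntimeError):
    """Fewer clean epochs are available than requested.

    Attributes
    ----------
    found : int
        Number of epochs that survived screening.
    requested : int
        Number of epochs that were asked for.
    """

    def __init__(self, found: int, requested: int):
        self.found = found
        self.requested = requested
        super().__init__(
            f"only {found} clean epochs available, {requested} requested"
        )


class DegeneratePhaseError(FCMSTError, ValueError):
    """Instantaneous phase is undefined (e.g. an all-zero channel)."""


class UndefinedEffectError(FCMSTError, ZeroDivisionError):
    """An effect size is undefined (zero pooled standard deviation)."""
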
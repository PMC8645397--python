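"""Exception types raised across the package."""


class KurticaError(ValueError):
    """Base class for validation and numerical-degeneracy failures."""


class InsufficientRankError(KurticaError):
    """Covariance rank is below the requested number of components."""

    def __init__(self, achieved_rank: int, requested: int):
        self.achieved_rank = achieved_rank
        self.requested = requested
        super().__init__(
            f"insufficient rank: covariance has rank {achieved_rank}, "
            f"but {requested} components were requested"
        )


class DegenerateSignalError(KurticaError):
    """A signal has zero (or numerically zero) variance."""


class ShapeMismatchError(KurticaError):
    """Array shapes of two objects that must agree do not."""
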
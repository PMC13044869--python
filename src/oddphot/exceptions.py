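"""Exception hierarchy.

All package errors derive from :class:`OddphotError` so callers (and the CLI)
can distinguish user/parameter errors from internal failures.
"""


class OddphotError(Exception):
    """Base class for all package errors."""


class ParameterError(OddphotError, ValueError):
    """A parameter is invalid (non-positive count, bad mode, ...)."""


class InfeasibleDesignError(OddphotError, ValueError):
    """The requested stimulus design cannot be constructed.

    E.g. a deviant probability too high for the minimum standard-run
    constraint.
    """


class DegenerateDataError(OddphotError, ValueError):
    """Input data are degenerate for the requested computation.

    E.g. zero-variance differences in a paired test, an all-constant trace
    for z-scoring, or an all-zero ratio.
    """


class NonPositiveReferenceError(OddphotError, ValueError):
    """The fitted reference trace contains non-positive samples."""

    def __init__(self, index: int):
        self.index = index
        super().__init__(
            f"fitted reference is non-positive at sample {index}; "
            "dF/F is undefined"
        )


class MissingWindowError(OddphotError, ValueError):
    """An epoch does not cover the analysis window of a component."""
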
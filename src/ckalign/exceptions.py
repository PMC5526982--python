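"""Exception hierarchy for ckalign.

All errors derive from :class:`CkalignError` so callers can catch the
package's failures with one clause; the concrete classes distinguish
contract violations (shapes, parameters) from degenerate-data conditions
that make the alignment statistic undefined.
"""


class CkalignError(Exception):
    """Base class for all ckalign errors."""


class ShapeError(CkalignError, ValueError):
    """Array dimensions do not chain or match."""


class ParameterError(CkalignError, ValueError):
    """A scalar or configuration parameter is out of its valid range."""


class DegenerateKernelError(CkalignError, ValueError):
    """A centered kernel is (numerically) zero, so the alignment is undefined.

    Raised for constant kernels — e.g. a Gaussian kernel whose bandwidth is
    so large that every entry is ~1 — and for single-class label kernels.
    """


class DegenerateLabelsError(DegenerateKernelError):
    """Fewer than two classes: the centered label kernel vanishes."""


class DegenerateGeometryError(CkalignError, ValueError):
    """All projected points coincide; no pairwise distance scale exists."""


class GroupingViolationError(CkalignError, ValueError):
    """A subject identifier spans a cross-validation fold or split boundary."""


class OptimizationError(CkalignError, RuntimeError):
    """Non-finite loss or other unrecoverable optimizer failure."""
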
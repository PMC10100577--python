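"""Exception hierarchy for the design pipeline and the trace analysis."""


class WirebundleError(Exception):
    """Base class for all package errors."""


class MeshFormatError(WirebundleError):
    """PLY parsing failed; the message names the offending element."""


class MeshValidationError(WirebundleError):
    """Mesh violates an invariant (bad index, non-manifold edge, ...)."""


class OrientationError(WirebundleError):
    """Face orientations cannot be made coherent (non-orientable input)."""


class RoutingError(WirebundleError):
    """Graph-level precondition of the router is not met."""


class NoATrailError(RoutingError):
    """Exhaustive backtracking proved no A-trail exists for this rotation
    system and doubling; carries the number of explored search states."""

    def __init__(self, message: str, explored: int = 0):
        super().__init__(message)
        self.explored = explored


class ScaleError(WirebundleError):
    """An edge maps to a degenerate base-pair length under the given scale."""


class NotReinforceableError(WirebundleError):
    """Edge at or below the reinforcement threshold."""


class GeometryError(WirebundleError):
    """No admissible crossover or end-loop placement exists."""


class InfeasibleError(WirebundleError):
    """A partition constraint (e.g. the 30-base oligo floor) cannot be met."""


class StapleDesignError(WirebundleError):
    """Staple coverage could not be completed under the length rules."""


class AssemblyError(WirebundleError):
    """Inconsistent cross-references while assembling the strand model."""


class CadnanoFormatError(WirebundleError):
    """Malformed caDNAno JSON or a non-reciprocal pointer; names the cell."""


class BudgetError(WirebundleError):
    """Scaffold shorter than the bases the design consumes."""


class AnalysisError(WirebundleError):
    """Trace-analysis precondition failed (too short, empty input, ...)."""


class FitRangeError(AnalysisError):
    """All tangent correlations fall below the usable fit range."""
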
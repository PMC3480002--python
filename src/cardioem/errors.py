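"""Exception hierarchy for cardioem."""


class CardioEMError(Exception):
    """Base class for all cardioem errors."""


class ConfigError(CardioEMError, ValueError):
    """Invalid run configuration; message enumerates the offending fields."""


class NonFiniteStateError(CardioEMError, ValueError):
    """A cell-state field contains NaN or infinity; names the field."""


class BlowUpError(CardioEMError, RuntimeError):
    """Membrane potential exceeded the |v| > 500 mV guard."""


class GateOvershootError(CardioEMError, RuntimeError):
    """A gating variable left [0, 1] by more than the clamping tolerance."""


class InvertedElementError(CardioEMError, RuntimeError):
    """An element Jacobian became non-positive (det F <= 0)."""


class WellPosednessError(CardioEMError, RuntimeError):
    """Mechanics requested without essential boundary conditions."""


class LinearSolverError(CardioEMError, RuntimeError):
    """Iterative or direct linear solve failed; carries the residual history."""

    def __init__(self, message, residuals=None):
        super().__init__(message)
        self.residuals = list(residuals) if residuals is not None else []
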
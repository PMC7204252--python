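"""Exception types shared across the package."""


class TkicomboError(Exception):
    """Base class for all package-specific errors."""


class InputError(TkicomboError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateParameterError(InputError):
    """PK parameters for which the two-exponential profile is singular (k_a == k_e)."""


class FitFailureError(TkicomboError, RuntimeError):
    """A root search or least-squares fit did not converge.

    Carries the residuals (if available) in ``residuals``.
    """

    def __init__(self, message, residuals=None):
        super().__init__(message)
        self.residuals = residuals


class MissingDataError(TkicomboError, KeyError):
    """A mutant/drug datum required by the computation is absent."""


class ModeMismatchError(InputError):
    """Interaction mode incompatible with the number or identity of drugs."""


class UnfittableCurveError(FitFailureError):
    """Dose-response data too degenerate for a median-effect or 4PL fit."""


class ConfigError(TkicomboError, ValueError):
    """A workflow configuration references unknown drugs, mutants or options."""
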
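"""Exception hierarchy.

All package errors derive from :class:`FoodDemandError` so callers can
catch one base class; the CLI maps subclasses onto distinct exit codes.
"""


class FoodDemandError(Exception):
    """Base class for all errors raised by this package."""


class ConfigError(FoodDemandError):
    """Invalid configuration or unknown option (CLI exit code 2)."""


class PanelValidationError(FoodDemandError):
    """Input data violates the panel schema or an invariant (exit code 3)."""


class FitError(FoodDemandError):
    """A regression failed (non-convergence, degenerate design; exit code 4)."""


class DomainError(FoodDemandError):
    """A model was evaluated outside its mathematical domain (exit code 4)."""


class ScenarioError(FoodDemandError):
    """Scenario projection or calibration failed (exit code 4)."""
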
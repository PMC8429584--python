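"""Exception types shared across the package."""


class SoccfError(Exception):
    """Base class for package errors."""


class ConfigurationError(SoccfError):
    """A packaged fixture or user configuration is malformed."""


class NoEquilibriumError(SoccfError):
    """The annual pool-update map has no fixed point (all decay shut off
    while carbon inputs are nonzero)."""


class NoCharacterizationFactorError(SoccfError, KeyError):
    """An elementary flow carries no SOC-depletion CF (water, wetland and
    bare-area flows are deliberately unmapped). Distinct from a CF of zero."""


class SimulationWarning(UserWarning):
    """Non-fatal simulation issues (e.g. a regeneration curve that did not
    reach its attainable stock within the simulation horizon)."""
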
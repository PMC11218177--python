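"""Exception types raised across the package."""


class ConfigurationError(ValueError):
    """A cohort/run configuration is internally inconsistent or out of range."""


class InputDataError(ValueError):
    """An input table or record violates the documented schema or invariants."""
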
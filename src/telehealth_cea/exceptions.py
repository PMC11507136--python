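"""Exception types shared across the pipeline."""


class ParameterError(ValueError):
    """A supplied parameter is outside its valid domain."""


class EstimationError(RuntimeError):
    """An estimate is undefined for the supplied data (e.g. zero person-years at risk)."""


class ConfigurationError(KeyError):
    """A configuration table is incomplete (e.g. a missing inflation rate)."""
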
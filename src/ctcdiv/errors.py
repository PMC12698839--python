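"""Exception hierarchy for the ctcdiv pipeline."""


class CtcDivError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(CtcDivError):
    """An invalid configuration value; the message names the offending field."""


class InputError(CtcDivError):
    """A malformed or inconsistent input file."""


class AnalysisError(CtcDivError):
    """A statistical precondition failed (empty group, zero events, ...)."""
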
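"""Exception hierarchy for the pipeline."""


class RareCnvError(Exception):
    """Base class for all package errors."""


class ParseError(RareCnvError, ValueError):
    """An input file could not be parsed; message names the file and line."""


class ConfigurationError(RareCnvError, ValueError):
    """Inputs and configuration are inconsistent (missing columns, thresholds
    on absent metrics, empty gene sets, ...)."""
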
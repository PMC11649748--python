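"""Exception hierarchy shared across the pipeline.

Configuration problems (bad thresholds, unknown weight keys, missing paths)
raise :class:`ConfigError`; malformed input data raises :class:`DataError`
or one of its subclasses. The CLI maps ConfigError to exit status 2 and
DataError to exit status 1.
"""


class PedsieveError(Exception):
    """Base class for all pipeline errors."""


class ConfigError(PedsieveError):
    """A configuration value or combination is invalid."""


class DataError(PedsieveError):
    """Input data is malformed or inconsistent."""


class ParseError(DataError):
    """A file could not be parsed; message names the offending line."""


class ValidationError(DataError):
    """Parsed data violates a structural invariant (e.g. pedigree cycle)."""


class CapacityError(PedsieveError):
    """An exact algorithm was asked to run beyond its enumeration bound."""
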
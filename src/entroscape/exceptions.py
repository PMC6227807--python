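"""Exception hierarchy.

``InputError`` flags bad data (values, shapes, labels); ``ConfigurationError``
flags bad run setup (missing columns, malformed scenario files). Both derive
from ``EntroscapeError`` so callers can catch everything from this package in
one clause.
"""


class EntroscapeError(Exception):
    """Base class for all errors raised by entroscape."""


class InputError(EntroscapeError, ValueError):
    """Invalid data passed to an operation."""


class ConfigurationError(EntroscapeError, ValueError):
    """Invalid run/scenario configuration."""
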
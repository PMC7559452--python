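"""Exception hierarchy.

``DataError`` marks malformed or internally inconsistent input data (CLI exit
code 2); ``CalibrationError`` marks an infeasible simulation configuration.
"""


class SmorfPredError(Exception):
    """Base class for all package-specific errors."""


class DataError(SmorfPredError):
    """Input data is malformed, inconsistent, or unusable."""


class CalibrationError(SmorfPredError):
    """A simulation configuration cannot realise the requested structure."""
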
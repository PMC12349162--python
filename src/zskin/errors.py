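"""Exception hierarchy.

Three error categories cross the CLI boundary with distinct prefixes:
validation (bad data), configuration (bad model/config), fitting
(estimation failure).
"""


class ZskinError(Exception):
    """Base class for all package errors."""

    category = "error"


class ValidationError(ZskinError):
    """Input data violates a documented invariant (bad spectrum, bad file)."""

    category = "validation"


class ConfigurationError(ZskinError):
    """Model topology, parameter set, or run configuration is inconsistent."""

    category = "configuration"


class FittingError(ZskinError):
    """Estimation could not produce any admissible result."""

    category = "fitting"
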
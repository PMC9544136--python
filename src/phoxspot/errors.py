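"""Exception hierarchy for the pipeline."""


class PhoxspotError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PhoxspotError):
    """A simulation or run configuration violates an invariant."""


class FormatError(PhoxspotError):
    """An input file does not conform to the expected schema."""


class CalibrationError(FormatError):
    """Coordinate units cannot be converted to microns."""


class ParameterError(PhoxspotError):
    """An analysis parameter is out of its valid range."""


class EmptyInputError(PhoxspotError):
    """A computation that requires at least one cell received none.

    Deliberately distinct from a legitimate 0% result.
    """
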
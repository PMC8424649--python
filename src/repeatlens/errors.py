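"""Exception hierarchy shared across modules."""


class RepeatLensError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(RepeatLensError, ValueError):
    """Invalid model or operation parameters."""


class FormatError(RepeatLensError, ValueError):
    """Malformed input file (missing columns, ragged alignment, ...)."""


class CalibrationError(RepeatLensError, ValueError):
    """Size-to-repeat conversion produced an impossible repeat count."""


class AmbiguityError(RepeatLensError, ValueError):
    """Expected alleles too close together to partition peaks safely."""


class CallError(RepeatLensError, ValueError):
    """Modal calling / index computation on an empty peak set."""


class PairingError(RepeatLensError, ValueError):
    """Two calls compared across incompatible allele windows."""


class FitError(RepeatLensError, ValueError):
    """Regression impossible (e.g. all sampling days identical)."""


class ConfigError(RepeatLensError, ValueError):
    """Invalid panel or fixture configuration."""


class SummaryError(RepeatLensError, ValueError):
    """Panel summary requested with no informative locus."""


class MappingError(RepeatLensError, KeyError):
    """Protein has no chain assignment in the structure map."""
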
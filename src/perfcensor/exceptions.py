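"""Exception hierarchy for perfcensor."""


class PerfcensorError(Exception):
    """Base class for all perfcensor errors."""


class FormatError(PerfcensorError):
    """Raster/table files are malformed or mutually inconsistent."""


class ConfigurationError(PerfcensorError):
    """Required acquisition metadata or configuration is missing/invalid."""


class ParameterError(PerfcensorError):
    """An operation parameter is out of its valid range."""


class DegenerateInputError(PerfcensorError):
    """Input is structurally valid but the requested quantity is undefined
    (empty mask, zero-variance table, zero-mean curve, ...)."""


class SubjectMismatchError(PerfcensorError):
    """Paired per-subject inputs do not describe the same subjects."""
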
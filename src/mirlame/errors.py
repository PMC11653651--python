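"""Exception hierarchy for the pipeline."""


class MirlameError(Exception):
    """Base class for all pipeline errors."""


class FormatError(MirlameError, ValueError):
    """A file on disk does not conform to the expected tabular dialect."""


class ValidationError(MirlameError, ValueError):
    """In-memory data violates a structural invariant (ids, ranges, joins)."""


class ConfigurationError(MirlameError, ValueError):
    """A simulation or pipeline configuration is internally inconsistent."""
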
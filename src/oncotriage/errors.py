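"""Exception hierarchy for the triage pipeline."""


class TriageError(Exception):
    """Base class for all pipeline errors."""


class FormatError(TriageError):
    """A file does not conform to its documented format."""


class ValidationError(TriageError):
    """Typed data violates a domain invariant (e.g. alt count > depth)."""


class ConfigError(TriageError):
    """A parameter or configuration value is out of its valid range."""
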
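"""Exception hierarchy for the pipeline."""


class MyelopanelError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(MyelopanelError, ValueError):
    """A record or parameter violates a documented invariant."""


class ConfigurationError(MyelopanelError, ValueError):
    """An input file or configuration is malformed (e.g. missing column)."""


class ClassificationError(MyelopanelError, RuntimeError):
    """A case cannot be classified (e.g. blast percentage unavailable)."""
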
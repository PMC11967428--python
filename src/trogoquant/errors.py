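"""Exception types shared across the pipeline."""


class TrogoquantError(Exception):
    """Base class for all package errors."""


class ValidationError(TrogoquantError):
    """Input data or parameters violate a documented contract."""


class GenerationError(TrogoquantError):
    """Synthetic field could not be generated under the requested parameters."""
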
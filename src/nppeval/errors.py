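"""Exception types distinguishing bad inputs from bad wiring."""


class ValidationError(ValueError):
    """Input data or parameters violate a documented precondition."""


class ConfigurationError(RuntimeError):
    """The pipeline or an algorithm is wired together inconsistently
    (shape mismatches, missing strategy handles, malformed config)."""
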
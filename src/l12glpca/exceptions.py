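"""Error types shared across the package."""


class InvalidConfigurationError(ValueError):
    """A parameter value violates the contract of an operation."""


class ContractViolationError(ValueError):
    """An input object breaks an invariant it was required to satisfy."""


class ParseError(ValueError):
    """A file could not be parsed into an expression matrix."""
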
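"""Exception hierarchy shared across the package."""


class TsrfError(Exception):
    """Base class for all package-specific errors."""


class ParseError(TsrfError):
    """Malformed input file (ragged rows, unparseable values)."""


class ValidationError(TsrfError):
    """Structurally well-formed input that violates a dataset invariant."""


class NoInformativeFeaturesError(TsrfError):
    """The stage-1 screen removed every feature at the given threshold."""
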
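"""Exception hierarchy shared across the toolkit.

``ConfigurationError`` covers invalid parameter combinations supplied by the
caller; ``DataError`` covers malformed or inconsistent input files; both map
onto distinct CLI exit codes.
"""


class NanohgtError(Exception):
    """Base class for all package errors."""


class ConfigurationError(NanohgtError):
    """Invalid configuration (bad fractions, unknown keys, inconsistent counts)."""


class DataError(NanohgtError):
    """Malformed or internally inconsistent input data."""


class ScreenInputError(DataError):
    """A filter is enabled but its required input is missing; names the filter."""

    def __init__(self, filter_name: str, detail: str = ""):
        self.filter_name = filter_name
        msg = f"input required by enabled filter '{filter_name}' is missing"
        if detail:
            msg += f": {detail}"
        super().__init__(msg)
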
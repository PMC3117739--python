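"""Exception hierarchy shared across the package."""


class RadbedError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(RadbedError, ValueError):
    """A radiobiological parameter is out of its physical domain."""


class DVHFormatError(RadbedError, ValueError):
    """A DVH file (or in-memory curve) violates the format contract."""


class DBFormatError(RadbedError, ValueError):
    """The parameter/constraint database file is malformed.

    Carries a list of ``(line_number, message)`` pairs in ``row_errors``.
    """

    def __init__(self, message: str, row_errors=None):
        super().__init__(message)
        self.row_errors = list(row_errors or [])


class LQValidityWarning(UserWarning):
    """Dose per fraction is beyond the range where the LQ model is trusted."""


class DVHShapeWarning(UserWarning):
    """A DVH operation was asked to do something degenerate but legal."""
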
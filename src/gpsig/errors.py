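"""Exception hierarchy.

Three classes map to the three CLI exit-code categories: usage errors are
handled by click itself (exit 2), :class:`DataError` exits 3, anything else
is an internal error and exits 4.
"""


class GpsigError(Exception):
    """Base class for all package errors."""


class DataError(GpsigError):
    """Invalid or inconsistent input data (bad file, violated precondition)."""


class DegenerateInputError(DataError):
    """Input is formally valid but the requested quantity is undefined on it
    (e.g. a median split when every sample has the same count, or a log-rank
    test with no events)."""
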
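"""Exception hierarchy shared across the package.

Two failure classes matter to callers (and map to distinct CLI exit codes):
malformed or inconsistent *input* versus a *statistical precondition* that
makes the requested estimate undefined (e.g. no healthy subjects to anchor
the risk ratio).
"""


class HrIndexError(Exception):
    """Base class for all package errors."""


class InputError(HrIndexError, ValueError):
    """Malformed input data or configuration (CLI exit code 2)."""


class PreconditionError(HrIndexError, ValueError):
    """A statistical precondition of the method is violated (CLI exit code 3)."""
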
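"""Exception hierarchy shared by all modules.

Exit-code mapping used by the CLI: 0 ok, 2 input contract violation,
3 structural ontology error.
"""


class GosumError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class InputError(GosumError, ValueError):
    """An input violates a documented contract (bad table, bad matrix,
    bad argument)."""

    exit_code = 2


class ParseError(InputError):
    """A flat file (OBO, GMT, TSV) is malformed; the message names the
    offending line where possible."""


class StructuralError(GosumError):
    """The ontology violates a structural requirement (cycle, zero or
    multiple roots, missing level stratum)."""

    exit_code = 3
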
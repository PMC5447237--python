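"""Exception hierarchy.

Two broad families matter to callers (and to the CLI exit codes):
input/validation problems (:class:`InputError`, exit code 2) and
numerical/graph problems discovered mid-computation (:class:`ComputeError`,
exit code 3).
"""


class CytomarkError(Exception):
    """Base class for all package errors."""


class InputError(CytomarkError):
    """Invalid user input: files, tables, parameters."""


class TableError(InputError):
    """Malformed or inconsistent cell-type/marker table."""


class FormatError(InputError):
    """Unreadable or malformed event data file."""


class ParameterError(InputError):
    """Out-of-range configuration parameter."""


class AlignmentError(InputError):
    """Samples whose marker panels do not line up."""


class ComputeError(CytomarkError):
    """Numerical or graph-structural failure during computation."""


class DegenerateFitError(ComputeError):
    """A marker mixture fit is unusable (single mode, vanishing weight...)."""


class GraphError(ComputeError):
    """Graph construction or connectivity violates a solver precondition."""
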
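"""Exception hierarchy shared across the toolkit.

Each family maps to a distinct CLI exit code (see :mod:`lidtraj.cli`), so
shell pipelines can distinguish malformed input from configuration problems
and from missing upstream artifacts.
"""


class LidtrajError(Exception):
    """Base class for all toolkit errors."""


class ParseError(LidtrajError):
    """A structure or trajectory file could not be parsed."""


class EmptyInputError(ParseError):
    """A coordinate file contained no atoms."""


class TopologyMismatchError(LidtrajError):
    """A trajectory frame disagrees with the topology atom count."""


class RegionError(LidtrajError):
    """A region definition does not resolve against the topology."""


class PartitionError(RegionError):
    """Decomposition regions overlap or fail to cover the selection."""


class SelectionError(LidtrajError):
    """An atom selection is empty after filtering."""


class DegenerateFitError(LidtrajError):
    """A superposition was requested on <3 atoms or a collinear set."""


class DependencyError(LidtrajError):
    """A pipeline stage is missing a required upstream artifact."""
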
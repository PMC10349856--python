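"""Exception hierarchy for model parsing and analysis."""


class RaflsboolError(Exception):
    """Base class for all package errors."""


class ModelSyntaxError(RaflsboolError):
    """Malformed model text; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class UndeclaredVariableError(RaflsboolError):
    """A rule references a node that is not declared in the network."""


class DuplicateTargetError(RaflsboolError):
    """The same target node is given more than one rule."""


class NameCollisionError(RaflsboolError):
    """A renaming maps two distinct nodes onto the same name."""


class UnboundVariableError(RaflsboolError):
    """Expression evaluation hit a variable absent from the state."""


class UnsupportedModelError(RaflsboolError):
    """SBML-qual construct outside the Boolean dialect (e.g. maxLevel > 1)."""


class CapacityError(RaflsboolError):
    """Exact analysis requested beyond the configured state-space budget."""


class ContradictorySeedError(RaflsboolError):
    """The same node seeded/clamped at two different values."""
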
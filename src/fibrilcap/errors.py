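"""Exception hierarchy for fibrilcap."""


class FibrilCapError(Exception):
    """Base class for all package errors."""


class StructureError(FibrilCapError):
    """Malformed, empty, or unwritable atomic structure."""


class SymmetryError(FibrilCapError):
    """Fibril layers cannot be grouped or a screw operator cannot be fitted."""


class BuildError(FibrilCapError):
    """Scaffold or fixture backbone generation failed."""


class DockError(FibrilCapError):
    """Grafting/superposition precondition violated."""


class ScoreError(FibrilCapError):
    """Scoring input invalid (unknown residue type, bad mutation string, ...)."""
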
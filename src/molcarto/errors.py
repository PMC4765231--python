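"""Exception and warning hierarchy.

All user-facing failures derive from :class:`MolcartoError` so callers (in
particular the CLI) can separate bad input from genuine bugs.
"""


class MolcartoError(Exception):
    """Base class for all expected, user-facing failures."""


class PdbParseError(MolcartoError):
    """A PDB file could not be parsed (no records, or a malformed field)."""


class FilterError(MolcartoError):
    """Atom filtering removed every atom."""


class FrameSeriesError(MolcartoError):
    """A directory of PDB frames could not be assembled into a series."""


class EmptyMouldError(MolcartoError):
    """Mould generation produced zero dummy atoms."""


class DegenerateMouldError(MolcartoError):
    """All mould points coincide with the centre of mass (radius 0)."""


class DatabaseError(MolcartoError):
    """A descriptor database file violates the documented schema."""


class UnknownDescriptorError(MolcartoError):
    """A descriptor name is absent from the registry."""


class UnpopulatedDescriptorError(MolcartoError):
    """The descriptor exists in the registry taxonomy but carries no values."""


class StageError(MolcartoError):
    """A pipeline stage failed; ``stage`` names the failing step."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"stage '{stage}' failed: {original}")


class MolcartoWarning(UserWarning):
    """Base warning category for recoverable oddities (multi-model files,
    points dropped at the centre of mass, lexicographic frame ordering...)."""
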
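"""Exception hierarchy.

Every error raised deliberately by this package derives from :class:`MprapError`,
so callers (and the CLI) can distinguish domain failures from programming bugs.
"""


class MprapError(Exception):
    """Base class for all package-level errors."""


class FormatError(MprapError):
    """A file does not conform to its expected dialect."""


class EmptyStructureError(MprapError):
    """No residues remain after filtering a structure file."""


class InvalidResidueError(MprapError):
    """A residue is unusable (e.g. has no atoms)."""


class UnknownResidueError(MprapError):
    """An amino-acid letter outside the 20 standard residues where one is required."""


class NotOrientedError(MprapError):
    """A membrane-frame operation was attempted on an unoriented structure."""


class DomainError(MprapError):
    """A numeric argument is outside its valid domain."""


class ConfigurationError(MprapError):
    """A reference table or schema is missing a required entry."""


class MissingDataError(MprapError):
    """A per-residue value required by an operation is absent."""


class AlignmentError(MprapError):
    """Per-residue inputs disagree in length or mapping."""


class InsufficientHomologsError(MprapError):
    """An alignment has fewer rows than required."""


class SchemaError(MprapError):
    """Feature vectors do not match a trained model's schema."""
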
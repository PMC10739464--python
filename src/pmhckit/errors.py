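"""Typed exceptions raised across the toolkit.

Every error a pipeline stage can raise deliberately derives from
:class:`PmhckitError`, so callers (and the CLI) can distinguish pipeline
failures from programming errors.
"""


class PmhckitError(Exception):
    """Base class for all toolkit errors."""


class StructureParseError(PmhckitError):
    """A structure file could not be read in the declared format."""


class EmptyStructureError(StructureParseError):
    """A parsed file contained no protein chains."""


class StandardizationError(PmhckitError):
    """Chains could not be unambiguously assigned to M/N/P (or M/B/P)."""


class NonCanonicalResidueError(PmhckitError):
    """A polymer residue is neither canonical nor in the modified-residue map."""


class AlphabetError(PmhckitError):
    """A sequence letter is outside the substitution-matrix alphabet."""


class ConfigurationError(PmhckitError):
    """Invalid or empty configuration input (e.g. empty reference set)."""


class AnchorError(PmhckitError):
    """User-supplied anchor positions violate the P1/P4/P6/P9 spacing."""


class CoreError(PmhckitError):
    """A binding core is invalid for its peptide."""


class PeptideLengthError(PmhckitError):
    """Peptide too short for the requested operation."""


class RestraintError(PmhckitError):
    """No usable anchor contacts to derive distance restraints from."""


class SelectionError(PmhckitError):
    """Template selection failed (e.g. empty template set)."""


class IncompleteBackboneError(PmhckitError):
    """A residue is missing one of the backbone atoms N, CA, C, O."""


class CorrespondenceError(PmhckitError):
    """Model and reference structures cannot be put in atom correspondence."""


class EvaluationError(PmhckitError):
    """L-RMSD evaluation preconditions violated (e.g. length mismatch)."""


class NumericalError(PmhckitError):
    """A numerical routine produced NaN/inf; the message names the term."""


class FixtureSpecError(PmhckitError):
    """A synthetic-fixture specification violates its invariants."""
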
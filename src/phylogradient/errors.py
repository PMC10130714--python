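"""Exception hierarchy.

All package errors derive from :class:`PhylogradientError` so callers can
catch one base class; validation problems (bad inputs, broken invariants)
are distinguished from runtime/domain problems for CLI exit codes.
"""


class PhylogradientError(Exception):
    """Base class for all package errors."""


class ValidationError(PhylogradientError):
    """Input fails a structural invariant (bad config, malformed table...)."""


class NewickParseError(ValidationError):
    """Newick text could not be parsed; message carries the offset reported
    by the parser."""


class UltrametricityError(ValidationError):
    """Tree is not ultrametric beyond tolerance; message names the worst tip."""


class UnknownSpeciesError(ValidationError):
    """Species names requested that are not tips of the phylogeny."""

    def __init__(self, offenders):
        self.offenders = sorted(offenders)
        super().__init__(
            "species not found in the phylogeny: " + ", ".join(self.offenders)
        )


class DomainError(PhylogradientError):
    """A numeric argument is outside its valid domain (e.g. slice depth)."""


class EmptyResultError(PhylogradientError):
    """An operation removed every row/cell, leaving nothing to analyse."""
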
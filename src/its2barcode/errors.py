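"""Exception hierarchy for the pipeline.

Every parser and operation rejects malformed input with a typed error rather
than silently repairing it; callers (and the CLI) can map each class to a
distinct exit message.
"""


class Its2BarcodeError(Exception):
    """Base class for all package errors."""


class FormatError(Its2BarcodeError):
    """Malformed file content (empty file, duplicate ids, bad characters)."""


class AlignmentError(FormatError):
    """Sequences that should share one coordinate axis do not."""


class StructureError(FormatError):
    """Invalid dot-bracket string (unbalanced or pseudoknotted)."""


class CrossReferenceError(Its2BarcodeError):
    """An id or axis referenced in one input is missing/incompatible in another."""


class AnnotationError(Its2BarcodeError):
    """Helix annotation inconsistent with the structure it labels."""


class UsageError(Its2BarcodeError):
    """A precondition on arguments was violated (bad threshold, too few taxa)."""


class UndefinedDistanceError(Its2BarcodeError):
    """A distance could not be computed (zero comparable positions)."""


class DataError(Its2BarcodeError):
    """Measurements violate their physical constraints."""


class UndefinedSensitivityError(DataError):
    """The reference strain shows no growth-rate decline, so the relative
    sensitivity scale is undefined."""


class SpecError(Its2BarcodeError):
    """A synthetic-data specification is infeasible."""
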
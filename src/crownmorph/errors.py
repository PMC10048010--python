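"""Exception hierarchy for crownmorph.

All package-specific errors derive from :class:`CrownMorphError`, so callers
can catch one base class; most also derive from ``ValueError`` because they
signal invalid inputs rather than internal failures.
"""


class CrownMorphError(Exception):
    """Base class for all crownmorph errors."""


class InvalidInputError(CrownMorphError, ValueError):
    """Non-finite coordinates, empty inputs, invalid parameters."""


class ShapeMismatchError(CrownMorphError, ValueError):
    """Configurations with incompatible point counts or tooth types."""


class DegenerateConfigurationError(CrownMorphError, ValueError):
    """Zero centroid size, duplicated landmarks, singular TPS systems."""


class TemplateValidationError(CrownMorphError, ValueError):
    """A configuration does not conform to its tooth template."""


class MissingToothError(CrownMorphError, ValueError):
    """A specimen is present for one tooth but missing for another."""


class SchemaError(CrownMorphError, ValueError):
    """Predictor columns or file fields do not match the expected layout."""


class PairingError(CrownMorphError, ValueError):
    """Repeat-digitization rounds cannot be paired specimen-by-specimen."""


class DegenerateTrainingError(CrownMorphError, ValueError):
    """Classifier training requested with a single class present."""


class ParseError(CrownMorphError, ValueError):
    """A landmark file could not be parsed; the message carries the line."""


class CurveClampWarning(UserWarning):
    """A slid semilandmark was clamped at a curve endpoint."""
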
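"""Exception hierarchy.

``ValidationError`` maps to CLI exit code 2 (bad input); everything else
raised by the package maps to exit code 1.
"""


class CrownClustError(Exception):
    """Base class for all errors raised by crownclust."""


class ValidationError(CrownClustError, ValueError):
    """Invalid user input: malformed files, out-of-range parameters."""


class ParseError(ValidationError):
    """A file could not be parsed; message names the offending line."""


class SchemaError(ValidationError):
    """A structured file is missing a required field."""


class EmptyInputError(ValidationError):
    """An input that must be non-empty was empty."""


class DegenerateTreeError(ValidationError):
    """A point cloud is too small or too flat to featurise."""
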
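"""Exception hierarchy for retrocap."""


class RetrocapError(Exception):
    """Base class for all package errors."""


class ConfigError(RetrocapError):
    """Invalid or inconsistent run configuration."""


class ParseError(RetrocapError):
    """A SMILES or reaction string could not be parsed."""


class IntegrityError(RetrocapError):
    """A reaction violates atom-map integrity (e.g. duplicate map numbers)."""


class TokenizationError(RetrocapError):
    """A character matched no SMILES token pattern."""


class AlignmentError(RetrocapError):
    """Token/atom alignment failed (count mismatch)."""


class ConformerError(RetrocapError):
    """3D embedding failed under the strict conformer policy."""


class LabelingError(RetrocapError):
    """Reaction-center labels cannot be derived (empty atom map)."""


class DataError(RetrocapError):
    """Malformed input data file."""


class TemplateError(RetrocapError):
    """Fragments incompatible with a reaction template."""
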
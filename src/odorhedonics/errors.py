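"""Exception hierarchy.

Every error raised on a contract violation derives from OdorHedonicsError so
callers can catch the package's failures with one clause.
"""


class OdorHedonicsError(Exception):
    """Base class for all package errors."""


class FormulaError(OdorHedonicsError):
    """Malformed or chemically impossible molecular formula."""


class StructureError(OdorHedonicsError):
    """SMILES could not be parsed or contradicts the formula."""


class UndeterminedFeatureError(OdorHedonicsError):
    """A tri-state acid/amine indicator is required but undetermined."""


class VocabularyError(OdorHedonicsError):
    """Descriptor missing from, or inconsistent with, a hedonic vocabulary."""


class ScalingError(OdorHedonicsError):
    """Autoscaling impossible (zero-variance column)."""


class TransformError(OdorHedonicsError):
    """Normalizing transform not applicable (negative values)."""


class DimensionError(OdorHedonicsError):
    """Requested more components/folds than the data support."""


class CollinearityError(OdorHedonicsError):
    """Singular or rank-deficient regression design."""


class ConfigError(OdorHedonicsError):
    """Invalid generator or pipeline configuration."""


class JoinError(OdorHedonicsError):
    """Identifier join between tables produced no rows."""
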
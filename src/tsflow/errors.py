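"""Exception types shared across the package."""


class TsflowError(Exception):
    """Base class for all package-specific errors."""


class ParseError(TsflowError):
    """A SMILES string could not be parsed into a molecule."""


class MappingError(TsflowError):
    """Atom maps are incomplete, inconsistent, or change element identity."""


class FormatError(TsflowError):
    """A file does not conform to its declared format (e.g. XYZ atom count)."""


class DatasetError(TsflowError):
    """A dataset table references geometries or fields that are missing."""


class FeatureError(TsflowError):
    """Featurization was requested for an unsupported element or atom pair."""


class InputError(TsflowError):
    """Array inputs have incompatible shapes or invalid values."""


class ConfigError(TsflowError):
    """A configuration is internally inconsistent or missing a requirement."""


class TrainingError(TsflowError):
    """Training diverged (non-finite loss)."""

    def __init__(self, message: str, epoch: int | None = None):
        super().__init__(message)
        self.epoch = epoch


class SamplingError(TsflowError):
    """ODE integration produced non-finite coordinates."""

    def __init__(self, message: str, step: int | None = None):
        super().__init__(message)
        self.step = step


class SplitError(TsflowError):
    """A dataset split cannot be constructed as requested."""


class SplitWarning(UserWarning):
    """Requested split fractions are unattainable; proceeding best-effort."""


class EmptyCoreError(TsflowError):
    """A reaction has no changed bond, hence no reaction core."""


class FixtureError(TsflowError):
    """The synthetic-fixture specification cannot be realized."""
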
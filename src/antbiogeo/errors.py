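"""Exception hierarchy for the antbiogeo package."""


class AntbiogeoError(Exception):
    """Base class for all package errors."""


class FormatError(AntbiogeoError):
    """A file or table does not have the required structure."""


class ValidationError(AntbiogeoError):
    """A value violates a data-model invariant."""


class ParameterError(AntbiogeoError):
    """An argument is outside its valid domain."""


class ConfigurationError(AntbiogeoError):
    """A simulation or pipeline configuration is invalid."""


class EstimationError(AntbiogeoError):
    """An estimation procedure cannot produce a result."""


class MappingError(AntbiogeoError):
    """A state set does not cover the observed data."""
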
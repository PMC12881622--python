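"""Exception hierarchy for the forestchange pipeline."""


class ForestChangeError(Exception):
    """Base class for all package errors."""


class ParameterError(ForestChangeError, ValueError):
    """A numeric or structural parameter is out of its documented range."""


class FormatError(ForestChangeError, ValueError):
    """A file or in-memory object violates the expected layout."""


class ConfigurationError(ForestChangeError, ValueError):
    """A scene or pipeline configuration is internally inconsistent."""


class EmptyMosaicError(ForestChangeError, ValueError):
    """No acquisitions fall inside the requested season window."""


class SchemaError(ForestChangeError, ValueError):
    """A feature table does not match the schema a model was trained on."""


class TrainingError(ForestChangeError, ValueError):
    """Training data cannot support fitting (e.g. a single class)."""


class SamplingError(ForestChangeError, ValueError):
    """Reference sampling cannot proceed (e.g. a change class has no polygon)."""
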
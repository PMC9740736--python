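"""Exception hierarchy: validation errors exit the CLI with code 1, runtime
errors with code 2."""


class PlantSegError(Exception):
    """Base class for package errors."""


class ValidationError(PlantSegError):
    """Invalid inputs, shapes, labels, or configuration values."""


class ParseError(ValidationError):
    """A point-cloud file that does not parse under the declared format."""


class ConfigError(ValidationError):
    """Inconsistent model or run configuration."""


class EvaluationError(PlantSegError):
    """Metric computation impossible (e.g. every class has an empty union)."""
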
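"""Exception hierarchy for the aeroalert pipeline."""


class AeroalertError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(AeroalertError):
    """A simulation or pipeline configuration is invalid."""


class GenerationError(AeroalertError):
    """Synthetic-data generation failed (e.g. missing weather for a night)."""


class ValidationError(AeroalertError):
    """Input data violate a documented invariant."""


class SelectionError(AeroalertError):
    """An action-night selection is undefined for the given inputs."""


class TrainingError(AeroalertError):
    """Forecast-model training cannot proceed."""
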
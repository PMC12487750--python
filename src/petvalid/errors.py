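"""Exception hierarchy for petvalid."""


class PetValidError(Exception):
    """Base class for all petvalid errors."""


class ConfigurationError(PetValidError):
    """Invalid configuration value (e.g. nonpositive half-life, unknown phantom)."""


class FillRecordError(PetValidError):
    """Inconsistent phantom fill accounting (e.g. residual exceeds pre-fill assay)."""


class DetectionError(PetValidError):
    """A sphere could not be located above the background level."""


class AnalysisError(PetValidError):
    """Invalid analysis input (ROI outside grid, radionuclide mismatch, ...)."""


class MetadataError(PetValidError):
    """Required image metadata (units, acquisition time) missing or inconsistent."""


class CriteriaError(PetValidError):
    """Criteria configuration or evaluation input invalid."""
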
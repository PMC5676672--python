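"""Exception hierarchy for the bioradar package."""


class BioradarError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(BioradarError, ValueError):
    """A scene or processing configuration violates its invariants."""


class MatrixFormatError(BioradarError, ValueError):
    """An on-disk echo matrix is malformed or inconsistent with its metadata."""


class ZeroEnergyError(BioradarError, ArithmeticError):
    """A wavelet energy distribution has zero total energy; the relative
    energy (probability) vector is undefined for that window."""


class PipelineError(BioradarError, RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnosis."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
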
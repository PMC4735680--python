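"""Exception hierarchy for cgmem."""


class CgmemError(Exception):
    """Base class for all cgmem errors."""


class ConfigurationError(CgmemError):
    """Inconsistent parameter set / system configuration."""


class GroParseError(CgmemError):
    """Malformed GRO coordinate file."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class TableFormatError(CgmemError):
    """Tabular file with missing or unit-mismatched columns."""


class ConvergenceError(CgmemError):
    """Iterative solver failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


class IntegrationError(CgmemError):
    """Non-finite energy/forces during time integration."""


class PackingError(CgmemError):
    """Random placement failed the minimum-distance rejection budget."""


class DegenerateBilayerError(CgmemError):
    """All lipids found on one side of the candidate midplane."""


class ResolutionError(CgmemError):
    """Surface grid too fine for the available lipid density."""


class SamplingError(CgmemError):
    """Monte-Carlo sampler degenerate (acceptance too low)."""


class FitError(CgmemError):
    """Not enough usable data for a requested fit."""
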
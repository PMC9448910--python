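"""Exception hierarchy shared across the package."""


class SpikeMapError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(SpikeMapError, ValueError):
    """A biophysical or grid parameter violates its domain (e.g. Cm <= 0)."""


class AlignmentError(SpikeMapError, ValueError):
    """Spike events are off the simulation grid or outside (0, T_w]."""


class RangeError(SpikeMapError, ValueError):
    """An encoder input lies outside the admissible range [0, 1]."""


class ShapeError(SpikeMapError, ValueError):
    """Mismatched tensor/list shapes or incompatible grids."""


class MappingDomainError(SpikeMapError, ValueError):
    """The ReLU<->LIF mapping is undefined for these parameters
    (requires 0 < sum(weights) < Vth*Cm when a bias is present)."""


class UnsupportedBiasError(MappingDomainError):
    """Positive biases have no leak-conductance counterpart here."""


class UndefinedCorrelationError(SpikeMapError, ValueError):
    """Pearson correlation is undefined (zero variance in an input)."""


class ValidationError(SpikeMapError, ValueError):
    """A network description fails structural validation."""


class FormatError(SpikeMapError, ValueError):
    """An on-disk artefact has an unknown version or malformed layout."""


class ConfigError(SpikeMapError, ValueError):
    """A fixture or run configuration is unsatisfiable."""
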
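"""Exception hierarchy shared across the package."""


class NMRTuneError(Exception):
    """Base class for all package errors."""


class BoundsError(NMRTuneError, ValueError):
    """Invalid search-space bounds (e.g. lower >= upper)."""


class ConfigurationError(NMRTuneError, ValueError):
    """Invalid configuration value or unknown identifier."""


class ShapeError(NMRTuneError, ValueError):
    """Dimension mismatch between genomes, schemas or arrays."""


class DecodeError(NMRTuneError, ValueError):
    """A genome value falls outside the decodable range of its gene."""


class LoaderError(NMRTuneError, ValueError):
    """A dataset file violates the loading contract."""


class EvaluationFailed(NMRTuneError, RuntimeError):
    """A classifier backend rejected a decoded configuration.

    The optimizer maps this to a sentinel-worst fitness instead of
    propagating the crash, so the search continues smoothly.
    """


class CalibrationError(NMRTuneError, RuntimeError):
    """Synthetic-data prevalence calibration could not reach its target."""
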
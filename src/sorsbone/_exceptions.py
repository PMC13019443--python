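"""Exception hierarchy shared across the package."""


class SorsBoneError(Exception):
    """Base class for all sorsbone errors."""


class FormatError(SorsBoneError):
    """Malformed spectral file (axis mismatch, bad shape)."""


class MetadataError(SorsBoneError):
    """Unparseable acquisition metadata (e.g. unknown position code)."""


class PairingError(SorsBoneError):
    """No transcutaneous/exposed-bone rows could be paired."""


class NormalizationError(SorsBoneError):
    """Band normalization impossible (zero or negative band maximum)."""


class RankError(SorsBoneError):
    """Requested number of latent components is infeasible."""


class DegeneracyError(SorsBoneError):
    """Degenerate design matrix (zero variance in every predictor)."""


class ConfigError(SorsBoneError):
    """Invalid generator or pipeline configuration."""


class MetricError(SorsBoneError):
    """Band metric undefined (missing band, non-positive denominator)."""

class StatTestError(SorsBoneError):
    """Too few subjects for the requested significance test."""


class RocError(SorsBoneError):
    """ROC analysis impossible (an empty class among scored subjects)."""
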
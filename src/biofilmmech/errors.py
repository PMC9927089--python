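"""Exception hierarchy for the biofilm-mechanics pipeline.

All package errors derive from :class:`BiofilmMechError` so callers (and the
pipeline's partial-failure policy) can catch them in one place.
"""


class BiofilmMechError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(BiofilmMechError, ValueError):
    """An input file does not match the expected dialect (missing column,
    shape mismatch, negative displacement span, ...)."""


class EmptyInputError(FormatError):
    """A file parsed to zero usable samples."""


class TooShortError(FormatError):
    """A curve has fewer samples than the analysis requires."""


class ConfigError(BiofilmMechError, ValueError):
    """A run configuration is incomplete or inconsistent."""


class DomainError(BiofilmMechError, ValueError):
    """A numeric argument lies outside the physical domain of an operation
    (non-positive angular velocity, non-positive modulus, empty window, ...)."""


class ContactNotFoundError(BiofilmMechError):
    """No sustained force rise qualifying as probe-biofilm contact."""


class WindowTooSmallError(BiofilmMechError, ValueError):
    """Too few samples fall inside the requested fit window."""


class DegenerateHistogramError(BiofilmMechError, ValueError):
    """Automatic thresholding is undefined (constant-intensity stack); use a
    fixed threshold instead."""


class UndefinedRoughnessError(BiofilmMechError, ValueError):
    """Roughness coefficient is undefined (all column heights are zero)."""


class PairingError(BiofilmMechError, ValueError):
    """Replicate pairing across treatment groups is impossible as requested."""


class InsufficientReplicatesError(BiofilmMechError, ValueError):
    """A group has too few replicates for the requested statistic."""
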
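"""Exception hierarchy for the mpradnv pipeline."""


class MpraError(Exception):
    """Base class for all mpradnv errors."""


class ConfigError(MpraError):
    """An invalid configuration value; the message names the offending field."""


class ReferenceMismatchError(MpraError):
    """The stated reference allele disagrees with the genome sequence."""


class BoundaryError(MpraError):
    """A requested window extends past a chromosome end."""


class SamplingError(MpraError):
    """Not enough items available to draw the requested sample."""


class FormatError(MpraError):
    """A malformed input file (BED, MEME, TSV...)."""


class ManifestError(MpraError):
    """Inconsistent library manifest (e.g. duplicate sequence ids)."""


class NormalizationError(MpraError):
    """Size factors cannot be computed (e.g. an all-zero library)."""


class DegenerateNullError(MpraError):
    """The negative-control null distribution is degenerate (MAD = 0)."""


class PipelineError(MpraError):
    """A pipeline stage failed or received unusable intermediate data."""
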
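"""Exception hierarchy for the appendix extraction pipeline.

Stage errors that represent an expected failure mode of the method
(degenerate contrast, missing fascia, no surviving candidate) derive from
:class:`StageFailure` so the pipeline driver can convert them into
structured failure records instead of crashing on clinically plausible
inputs.
"""


class AppendixUSError(Exception):
    """Base class for all package errors."""


class ImageFormatError(AppendixUSError):
    """File could not be read as a supported raster format."""


class DimensionError(AppendixUSError):
    """Raster has an invalid or mismatched shape."""


class ConfigError(AppendixUSError):
    """A configuration key is unknown or outside its documented range."""


class PhantomSpecError(AppendixUSError):
    """Phantom geometry is inconsistent (e.g. appendix above the fascia)."""


class StageFailure(AppendixUSError):
    """An expected, reportable failure of a pipeline stage."""

    stage: str = "unknown"


class DegenerateContrastError(StageFailure):
    """Image has a single brightness value; stretch bounds are undefined."""

    stage = "stretch"


class FasciaNotFoundError(StageFailure):
    """No connected component qualifies as a fascia band."""

    stage = "fascia"


class NoClustersError(StageFailure):
    """Winner selection requested before any cluster was committed."""

    stage = "fuzzyart"


class NoPixelsError(StageFailure):
    """Clustering was asked to run on an empty region of interest."""

    stage = "fuzzyart"


class NoCandidateError(StageFailure):
    """No region survived dark-cluster binarization, erosion and the
    area filter; mirrors the method's reported failure mode on
    low-contrast images."""

    stage = "extract"
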
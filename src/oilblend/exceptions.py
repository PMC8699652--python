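"""Exception hierarchy.

Everything raised deliberately by the package derives from
:class:`OilblendError`, so callers can catch one type at a pipeline
boundary while tests can still assert on the specific failure.
"""


class OilblendError(Exception):
    """Base class for all package errors."""


class FormatError(OilblendError):
    """A spectral table is malformed (missing column, unparsable cell)."""


class GridError(OilblendError):
    """Wavelength grid is invalid (non-monotone, duplicates, non-positive)."""


class ValidationError(OilblendError):
    """A SpectrumSet violates its type invariants."""


class ParameterError(OilblendError):
    """An operation was called with infeasible parameters."""


class FitError(OilblendError):
    """A model or pretreatment could not be fitted (degenerate input)."""


class DegenerateSpectrumError(OilblendError):
    """A per-spectrum transform hit a spectrum it cannot correct."""


class CorrectionError(OilblendError):
    """Scatter correction failed for a specific sample."""


class LabellingError(OilblendError):
    """A sample's mixing ratio is not on the design lattice."""


class SelectionError(OilblendError):
    """A wavelength-selection algorithm could not produce a subset."""


class ConfigError(OilblendError):
    """A pipeline configuration is inconsistent."""
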
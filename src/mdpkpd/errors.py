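"""Exception hierarchy for the microdialysis PK-PD pipeline.

Every error raised on bad scientific input derives from :class:`MdpkpdError`
so callers (and the CLI) can distinguish analysis failures from bugs.
"""


class MdpkpdError(Exception):
    """Base class for all analysis errors."""


class SchemaError(MdpkpdError):
    """An input table is missing required columns or has inconsistent units."""


# --- calibration ---------------------------------------------------------

class CalibrationUnderdeterminedError(MdpkpdError):
    """Fewer than three distinct concentrations in a calibration range."""


class DegenerateDesignError(MdpkpdError):
    """Zero concentration variance: the regression design is singular."""


class InvalidSlopeError(MdpkpdError):
    """Calibration slope is non-positive; detection limits are undefined."""


class UndefinedRsdError(MdpkpdError):
    """Mean of replicate measurements is zero; RSD is undefined."""


class InvalidReferenceError(MdpkpdError):
    """Reference (solvent) peak areas average to zero or less."""


# --- probe recovery ------------------------------------------------------

class ImplausibleRecoveryError(MdpkpdError):
    """A replicate recovery exceeds 1.2 — likely a unit mismatch."""


class InvalidRecoveryError(MdpkpdError):
    """Recovery fraction outside (0, 1]; correction is undefined."""


class NoDataError(MdpkpdError):
    """An aggregation was requested on an empty table."""


# --- NCA and model fitting -----------------------------------------------

class InsufficientDataError(MdpkpdError):
    """Too few observations for the requested computation."""


class DegenerateRateError(MdpkpdError):
    """Absorption and elimination rate constants coincide (ka == ke)."""


class FitFailedError(MdpkpdError):
    """The optimiser failed to converge from every starting point."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class UnidentifiableError(MdpkpdError):
    """The data carry no information on the requested parameters
    (e.g. flat effect series, degenerate concentration range)."""


class NormalizationError(MdpkpdError):
    """Baseline is zero or negative; percent-of-baseline is undefined."""


class ConfigError(MdpkpdError):
    """Simulation configuration failed validation."""

    def __init__(self, message: str, fields: list[str] | None = None):
        super().__init__(message)
        self.fields = fields or []
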
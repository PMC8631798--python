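"""Exception types shared across the package."""


class DivtraceError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(DivtraceError, ValueError):
    """A configuration value is missing, malformed, or out of range.

    The message names the offending field.
    """


class InfeasibleRateError(DivtraceError, ValueError):
    """An observed double-labelling rate exceeds the maximum the assumed
    transfer efficiency can produce (r >= e / (2 - e)).

    Attributes
    ----------
    observed_rate : float
        The offending observed rate r.
    efficiency : float
        The assumed per-jump transfer efficiency e.
    bound : float
        The feasibility bound e / (2 - e).
    implied_min_efficiency : float
        The smallest efficiency consistent with the observed rate,
        2 r / (1 + r).
    """

    def __init__(self, observed_rate: float, efficiency: float):
        self.observed_rate = float(observed_rate)
        self.efficiency = float(efficiency)
        self.bound = efficiency / (2.0 - efficiency)
        self.implied_min_efficiency = (
            2.0 * observed_rate / (1.0 + observed_rate)
        )
        super().__init__(
            f"observed rate {observed_rate:.6g} is at or above the maximum "
            f"observable rate e/(2-e) = {self.bound:.6g} for efficiency "
            f"e = {efficiency:.6g}; the smallest efficiency consistent with "
            f"this rate is {self.implied_min_efficiency:.6g}"
        )


class PipelineError(DivtraceError, RuntimeError):
    """A pipeline stage cannot proceed (e.g. empty input table)."""
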
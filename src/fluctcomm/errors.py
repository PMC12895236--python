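"""Exception hierarchy for fluctcomm."""


class FluctcommError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(FluctcommError, ValueError):
    """Invalid or inconsistent model parameters."""


class ConfigError(FluctcommError, ValueError):
    """Invalid experiment configuration; message lists offending fields."""

    def __init__(self, problems):
        if isinstance(problems, str):
            problems = [problems]
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))


class IntegrationError(FluctcommError, RuntimeError):
    """Numerical integration produced NaN/overflow; names the failing step."""


class EstimationError(FluctcommError, RuntimeError):
    """Time series too short or otherwise unsuitable for estimation."""


class NormalizationError(FluctcommError, ValueError):
    """Distribution cannot be normalized (improper parameter limit)."""


class FitError(FluctcommError, RuntimeError):
    """Maximum-likelihood fit failed to converge or input was degenerate."""
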
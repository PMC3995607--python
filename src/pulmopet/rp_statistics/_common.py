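"""Shared constants and exceptions for the outcome-statistics battery."""

#: z-multiplier for 95% Wald confidence intervals throughout.
Z95 = 1.96

#: Default two-sided significance level.
ALPHA = 0.05


class ModelFitError(RuntimeError):
    """A regression model could not be fit (separation, monotone likelihood...)."""
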
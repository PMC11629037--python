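"""Exception hierarchy shared across the pipeline."""


class PhenovalError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(PhenovalError):
    """Invalid configuration: bad value set, infeasible cohort spec, bad window."""


class DataError(PhenovalError):
    """Invalid or missing input data (e.g. a required NDJSON file is absent)."""


class UndefinedStatisticError(PhenovalError):
    """A statistic whose defining formula is degenerate for the given input.

    Raised instead of silently returning 0 or NaN, e.g. a PPV with an empty
    denominator, Cohen kappa when expected agreement is exactly 1, or a pooled
    two-sample z test whose pooled proportion is 0 or 1.
    """
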
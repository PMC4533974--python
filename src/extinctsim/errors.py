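"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A simulation or schedule parameter is out of its legal range."""


class EmptyPopulationError(ValueError):
    """An operation that requires organisms was given none."""


class UndefinedStatisticError(ValueError):
    """A statistic is undefined for the given sample (e.g. zero rank variance)."""
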
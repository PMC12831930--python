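"""Exception types shared across the package."""


class FormatError(ValueError):
    """An input file does not conform to its declared format."""


class UndefinedStatisticError(ValueError):
    """A statistic is undefined for the given input (e.g. constant values)."""
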
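"""Exception taxonomy used across the package.

``ConfigError`` marks invalid user configuration (bad ratios, unknown views,
out-of-range rates); ``DataError`` marks inputs whose content violates a
precondition (all-missing columns, unpairable samples); ``FormatError``
marks malformed files; ``NumericError`` marks degenerate numerical inputs
(zero vectors, non-finite losses).
"""


class LeopardError(Exception):
    pass


class ConfigError(LeopardError):
    pass


class DataError(LeopardError):
    pass


class FormatError(DataError):
    pass


class NumericError(LeopardError):
    pass
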
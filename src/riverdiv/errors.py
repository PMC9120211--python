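"""Exception types shared across the pipeline."""


class RiverdivError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(RiverdivError, ValueError):
    """A simulation or analysis configuration violates its invariants."""


class InvalidInputError(RiverdivError, ValueError):
    """An input object (table, geometry, tree) violates a precondition."""


class DegenerateIndicatorError(RiverdivError, ValueError):
    """An indicator table is identically zero and cannot be standardized."""
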
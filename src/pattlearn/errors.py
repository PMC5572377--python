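"""Exception hierarchy shared across the package."""


class PattlearnError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(PattlearnError, ValueError):
    """Invalid parameter values, malformed inputs, or broken invariants."""


class DegeneratePatternError(PattlearnError, ValueError):
    """A voxel pattern (or statistic input) has zero variance and no
    correlation is defined for it."""


class DegenerateInputError(PattlearnError, ValueError):
    """A statistical routine received an input (e.g. a constant vector)
    on which its sampling distribution is undefined."""


class InfeasibleDesignError(PattlearnError, RuntimeError):
    """No event schedule satisfying the spacing constraints was found
    within the configured restart budget."""


class ParseError(PattlearnError, ValueError):
    """A tabular or volumetric input file failed schema validation."""
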
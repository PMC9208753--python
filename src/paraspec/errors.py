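"""Exception types shared across the package."""


class ParaspecError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(ParaspecError, ValueError):
    """An argument violates a documented precondition."""


class InvalidInputError(ParaspecError, ValueError):
    """An input file or record set violates its schema or invariants."""


class FormatError(InvalidInputError):
    """A file could not be parsed in the expected format."""


class NewickParseError(FormatError):
    """Malformed Newick text."""


class MissingSequenceError(ParaspecError, KeyError):
    """A required sequence id is absent from an alignment."""

    def __str__(self) -> str:  # KeyError quotes its message by default
        return self.args[0] if self.args else ""


class InvalidModelError(ParaspecError, ValueError):
    """A substitution model violates its invariants."""


class NonMonophyleticOutgroupError(ParaspecError, ValueError):
    """The requested outgroup does not form a clade in the unrooted tree."""


class WildTypeMismatchError(ParaspecError, ValueError):
    """A substitution's stated wild-type residue disagrees with the sequence."""


class MissingTimepointError(ParaspecError, ValueError):
    """No observation exists near the requested time."""


class InsufficientDataError(ParaspecError, ValueError):
    """Too few usable observations for the requested estimate."""


class UndefinedRatioError(ParaspecError, ValueError):
    """A specificity ratio was requested with a non-positive rate."""
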
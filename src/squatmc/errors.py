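"""Exception hierarchy shared across the package."""


class SquatMCError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(SquatMCError):
    """A domain object violates one of its invariants."""


class ConfigurationError(SquatMCError):
    """A configuration file or argument set is incomplete or inconsistent."""


class ParseError(SquatMCError):
    """A motion/model file could not be parsed; message names the location."""


class ModelLookupError(SquatMCError, KeyError):
    """An identifier (muscle, segment, DoF, group) does not exist in a model."""


class SolverError(SquatMCError):
    """A numerical routine failed in a way that cannot be flagged and skipped."""
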
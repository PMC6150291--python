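"""Exception hierarchy shared across the package."""


class QuenchBindError(Exception):
    """Base class for all errors raised by quenchbind."""


class ValidationError(QuenchBindError, ValueError):
    """A domain object violates one of its invariants."""


class ParseError(QuenchBindError, ValueError):
    """A text input file could not be parsed; the message names the offending line."""


class FitError(QuenchBindError, ValueError):
    """A regression cannot be performed on the supplied data."""


class CorrectionError(QuenchBindError, ValueError):
    """Inner-filter correction was mis-applied (missing absorbances, double correction...)."""


class PipelineError(QuenchBindError, RuntimeError):
    """A pipeline stage failed; the message names the stage and the offending input."""
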
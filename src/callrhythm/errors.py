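"""Exception hierarchy shared across the pipeline."""


class CallRhythmError(Exception):
    """Base class for all package errors."""


class SchemaError(CallRhythmError):
    """An input table is missing a required column or has a wrong dtype."""


class ValidationError(CallRhythmError):
    """An input table violates an invariant (ordering, ties, labels)."""


class FitError(CallRhythmError):
    """A model fit failed or produced an inadmissible result."""


class CouplingError(CallRhythmError):
    """A coupling statistic is undefined for the given series."""
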
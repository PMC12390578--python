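"""Exception hierarchy for bioassay data handling and analysis."""


class BioassayError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(BioassayError):
    """A tabular input is missing required columns or has a malformed header."""


class ValidationError(BioassayError):
    """A record violates a data invariant (monotonicity, count bounds, ...)."""


class GroupingError(BioassayError):
    """Records passed to an aggregation do not form a single strain/treatment group."""


class NoDiagnosticTimeError(BioassayError):
    """The susceptible reference never reached 100% mortality within the assay window."""


class UndefinedCorrectionError(BioassayError):
    """Abbott's correction is undefined (control mortality at 100%)."""
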
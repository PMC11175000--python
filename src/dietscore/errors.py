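"""Exception hierarchy shared by all dietscore modules."""


class DietscoreError(Exception):
    """Base class for all package errors."""


class SchemaError(DietscoreError):
    """Malformed or inconsistent questionnaire schema / rules file."""


class ReadError(DietscoreError):
    """Response file could not be parsed into profiles."""


class ScoringError(DietscoreError):
    """A scoring rule could not be evaluated for a profile."""


class DomainError(DietscoreError):
    """An input value lies outside the domain an operation accepts."""


class DegenerateDataError(DietscoreError):
    """A statistic is undefined on the given data (e.g. constant vector)."""
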
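"""Exception hierarchy for the MTB engine.

Exit-code classes for the CLI: validation errors (2), workflow errors (3),
I/O and format errors (4).
"""


class MtbError(Exception):
    """Base class for all engine errors."""


class ValidationFailure(MtbError):
    """A domain object violates its invariants.

    ``violations`` holds human-readable descriptions, each naming the
    offending field.
    """

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__("; ".join(self.violations) or "validation failed")


class DuplicateCaseError(MtbError):
    """A case with this pseudonym already exists in the store."""


class UnknownEvidenceLevelError(MtbError):
    """Evidence level is not a member of the configured scale."""


class UnknownVariantError(MtbError):
    """Annotation references a variant key absent from the case."""


class WorkflowError(MtbError):
    """Base class for lifecycle errors."""


class IllegalTransitionError(WorkflowError):
    """The (from, to) state pair is not in the allowed transition set."""

    def __init__(self, from_state, to_state):
        self.from_state = from_state
        self.to_state = to_state
        super().__init__(f"illegal transition {from_state.value} -> {to_state.value}")


class GuardError(WorkflowError):
    """A transition is allowed in principle but its guard artifact is missing."""


class WrongStateError(WorkflowError):
    """Operation requires the case to be in a different state."""


class CapacityExceededError(WorkflowError):
    """Meeting already holds its configured number of cases."""


class MissingMeetingError(WorkflowError):
    """Follow-up timing requires a scheduled meeting date."""


class MissingDocumentationError(WorkflowError):
    """Documentation report requested for an undocumented case."""


class MissingPanelSizeError(MtbError):
    """Mutation burden requires a positive panel size in megabases."""


class FormatError(MtbError):
    """Base class for file-format errors."""


class MissingColumnError(FormatError):
    """A required column is absent from a variant table."""

    def __init__(self, column):
        self.column = column
        super().__init__(f"missing required column: {column!r}")


class TableParseError(FormatError):
    """A data row of a variant table failed to parse; carries the line number."""

    def __init__(self, line, message):
        self.line = line
        super().__init__(f"line {line}: {message}")


class VcfParseError(FormatError):
    """The VCF file could not be parsed."""


class SnapshotParseError(FormatError):
    """A knowledge-snapshot line failed to parse; carries the line number."""

    def __init__(self, line, message):
        self.line = line
        super().__init__(f"line {line}: {message}")


class SchemaViolationError(FormatError):
    """A case file violates the case schema; carries the violation list."""

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__("; ".join(self.violations) or "schema violation")


class InvalidConfigError(FormatError):
    """A configuration value is invalid; the message names the key."""


class InfeasibleParametersError(MtbError):
    """Synthetic-cohort constraints could not be met within bounded resampling."""
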
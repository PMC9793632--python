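"""Exception hierarchy shared across the engine.

Every error carries a short machine-readable ``code`` so callers (and the
CLI) can branch on the failure kind without parsing messages.
"""

from __future__ import annotations


class Nof1Error(Exception):
    """Base class for all engine errors."""

    code: str = "error"

    def __init__(self, message: str, *, code: str | None = None):
        super().__init__(message)
        if code is not None:
            self.code = code


class TrialParseError(Nof1Error):
    """Input is not syntactically valid JSON."""

    code = "parse_error"


class TrialSchemaError(Nof1Error):
    """Valid JSON that does not match the trial document schema.

    ``paths`` lists the offending locations (dotted, e.g. ``"measures"`` or
    ``"interventions.0.reminder"``).
    """

    code = "schema_error"

    def __init__(self, message: str, paths: list[str] | None = None):
        super().__init__(message)
        self.paths = paths or []


class InvalidTrialError(Nof1Error):
    """A structurally parseable trial that fails domain validation.

    Raised by operations whose precondition is a *valid* trial; the full
    violation list is attached as ``report``.
    """

    code = "invalid_trial"

    def __init__(self, message: str, report=None):
        super().__init__(message)
        self.report = report


class RecordingError(Nof1Error):
    """A measurement entry rejected by the measure's input-type rules.

    Codes: ``unknown_measure``, ``unparsable_number``, ``invalid_item``,
    ``scale_out_of_range``, ``outside_trial``.
    """


class CsvImportError(Nof1Error):
    """Malformed observation CSV; ``row_errors`` maps line number -> message."""

    code = "csv_import"

    def __init__(self, message: str, row_errors: list[tuple[int, str]]):
        super().__init__(message)
        self.row_errors = row_errors


class TaskError(Nof1Error):
    """Illegal task-log operation (codes: ``unknown_task``, ``not_pending``)."""


class SummaryError(Nof1Error):
    """Aggregation request that the measure's type or data cannot support.

    Codes: ``non_numeric_measure``, ``non_list_measure``,
    ``insufficient_data``.
    """
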
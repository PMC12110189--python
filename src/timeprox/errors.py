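"""Typed exceptions used across the pipeline.

Every malformed input raises one of these; nothing is silently dropped.
The CLI maps them onto exit codes (schema/validation -> 2, statistical
degeneracy -> 3, anything else -> 4).
"""


class TimeproxError(Exception):
    """Base class for all package errors."""


class SchemaError(TimeproxError):
    """A required column or field is missing or has the wrong type."""


class TableValidationError(TimeproxError):
    """A row violates an invariant (negative intensity, pfs > os, ...)."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)


class IntegrityError(TimeproxError):
    """Internally inconsistent state (e.g. cells counted in a zero-area region)."""


class StatisticalDegeneracyError(TimeproxError):
    """A statistical routine was handed data it cannot meaningfully analyse."""


class StageError(TimeproxError):
    """A pipeline stage failed; carries the stage name for the manifest."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
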
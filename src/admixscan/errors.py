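"""Exception hierarchy for the admixscan pipeline."""


class AdmixscanError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(AdmixscanError):
    """A simulation or pipeline configuration violates its invariants."""


class AlignmentError(AdmixscanError):
    """Arrays that must be aligned to the marker panel are not."""


class SchemaError(AdmixscanError):
    """A file violates its documented schema.

    Carries the offending column and (1-based) line number when known.
    """

    def __init__(self, message: str, column: str | None = None, line: int | None = None):
        self.column = column
        self.line = line
        loc = []
        if column is not None:
            loc.append(f"column {column!r}")
        if line is not None:
            loc.append(f"line {line}")
        if loc:
            message = f"{message} ({', '.join(loc)})"
        super().__init__(message)


class EstimationError(AdmixscanError):
    """Ancestry estimation failed (no informative markers, zero-probability model)."""


class DecompositionError(AdmixscanError):
    """A percent-explained decomposition is undefined for the given inputs."""
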
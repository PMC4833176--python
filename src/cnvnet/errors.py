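"""Exception hierarchy shared across the package."""


class CnvnetError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CnvnetError):
    """A file or parameter is structurally unusable (e.g. missing column)."""


class RecordError(CnvnetError):
    """One or more input rows violate a record-level invariant.

    Carries the offending (line_number, message) pairs so callers can
    report every bad row at once instead of failing on the first.
    """

    def __init__(self, message: str, bad_rows: list[tuple[int, str]] | None = None):
        self.bad_rows = bad_rows or []
        if self.bad_rows:
            detail = "; ".join(f"line {ln}: {msg}" for ln, msg in self.bad_rows[:20])
            message = f"{message} ({detail})"
        super().__init__(message)


class OntologyError(CnvnetError):
    """The phenotype ontology violates a structural invariant (e.g. a cycle)."""


class NoAnalyzableGenesError(CnvnetError):
    """No query gene intersects the annotated universe, so no test can run."""
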
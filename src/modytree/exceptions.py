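"""Exception hierarchy shared across the pipeline stages.

Every error raised on a domain precondition derives from :class:`ModyTreeError`
so the CLI can map them onto a single exit status with a module-prefixed,
machine-readable category line.
"""


class ModyTreeError(Exception):
    """Base class for all domain errors raised by this package."""

    #: short machine-readable category used by the CLI error line
    category: str = "error"


class CohortFormatError(ModyTreeError):
    """The cohort table is structurally invalid (e.g. a required column is absent)."""

    category = "cohort_model.format"


class CohortValidationError(ModyTreeError):
    """One or more rows violate a hard invariant.

    ``diagnostics`` is a list of ``(row_index, message)`` pairs, where
    ``row_index`` is the 0-based data-row index (header excluded).
    """

    category = "cohort_model.validation"

    def __init__(self, diagnostics):
        self.diagnostics = list(diagnostics)
        lines = "; ".join(f"row {i}: {msg}" for i, msg in self.diagnostics)
        super().__init__(f"{len(self.diagnostics)} invalid row(s): {lines}")


class ConfigurationError(ModyTreeError):
    """A simulation or pipeline configuration is incomplete or inconsistent."""

    category = "synthetic_cohort.config"


class SeparationError(ModyTreeError):
    """Complete or quasi-complete separation in a logistic fit."""

    category = "logistic_index.separation"

    def __init__(self, markers, detail=""):
        self.markers = tuple(markers)
        msg = f"separation detected for marker(s) {', '.join(self.markers)}"
        if detail:
            msg += f" ({detail})"
        super().__init__(msg)


class SingularDesignError(ModyTreeError):
    """The logistic design matrix is rank deficient."""

    category = "logistic_index.singular"


class MissingMarkerError(ModyTreeError):
    """A record lacks a marker value required by an index or tree."""

    category = "missing_marker"

    def __init__(self, marker, record_id):
        self.marker = marker
        self.record_id = record_id
        super().__init__(f"record {record_id!r} is missing marker {marker!r}")


class DegenerateDiscriminationError(ModyTreeError):
    """No candidate group can be discriminated better than chance at a tree step."""

    category = "tree_builder.degenerate"


class SmallSampleError(ModyTreeError):
    """A group has fewer records than the minimum required to fit a tree step."""

    category = "tree_builder.small_sample"
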
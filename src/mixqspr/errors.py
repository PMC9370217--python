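"""Exception hierarchy shared across the package."""


class MixQSPRError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(MixQSPRError):
    """A dataset or descriptor file violates the documented column schema."""

    def __init__(self, message: str, row: int | None = None, field: str | None = None):
        self.row = row
        self.field = field
        detail = message
        if row is not None:
            detail += f" (row {row}"
            detail += f", field '{field}')" if field else ")"
        elif field:
            detail += f" (field '{field}')"
        super().__init__(detail)


class UnknownComponentError(MixQSPRError):
    """A mixture references a component id absent from the descriptor table."""

    def __init__(self, component_id: str):
        self.component_id = component_id
        super().__init__(f"component '{component_id}' not found in descriptor table")


class DegenerateSplitError(MixQSPRError):
    """A (seed, interval) selection empties the training or the test set."""


class SingularityError(MixQSPRError):
    """The design matrix is rank deficient."""

    def __init__(self, dependent_columns):
        self.dependent_columns = list(dependent_columns)
        cols = ", ".join(self.dependent_columns) or "<unknown>"
        super().__init__(f"rank-deficient design; linearly dependent column(s): {cols}")


class MissingFeatureError(MixQSPRError):
    """A model feature is absent from the supplied feature matrix."""

    def __init__(self, feature: str):
        self.feature = feature
        super().__init__(f"feature column '{feature}' missing from feature matrix")
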
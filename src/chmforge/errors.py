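"""Exception hierarchy shared across the package."""


class ChmForgeError(Exception):
    """Base class for all chmforge errors."""


class FormatError(ChmForgeError):
    """A file is not in a recognized or well-formed format."""


class ValidationError(ChmForgeError):
    """Inputs or options are inconsistent with the current build state."""


class SizeLimitError(ValidationError):
    """The matrix exceeds the clustering size gate (rows + columns)."""

    def __init__(self, n_rows: int, n_cols: int, limit: int):
        self.n_rows = n_rows
        self.n_cols = n_cols
        self.limit = limit
        super().__init__(
            f"matrix has {n_rows} rows + {n_cols} columns = {n_rows + n_cols}, "
            f"which exceeds the clustering limit of {limit}; "
            f"filter rows or columns before clustering"
        )
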
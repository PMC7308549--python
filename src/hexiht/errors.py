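"""Exception types shared across the pipeline."""


class SchemaError(ValueError):
    """An input table is missing a required column or uses an unknown label."""


class ParseError(ValueError):
    """A cell value could not be parsed; carries the offending row index."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class ConfigError(ValueError):
    """A parameter or piece of required configuration is invalid or absent."""


class UndefinedIndicatorError(Exception):
    """An indicator is undefined on this input (distinct from a zero value).

    ``reason`` is a short machine-readable code, e.g. ``no_evaluable_cells``,
    ``no_adjacent_pairs``, ``too_few_hexagons``, ``no_admissible_split``.
    """

    def __init__(self, reason: str, message: str | None = None):
        super().__init__(message or reason)
        self.reason = reason
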
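"""Exception types shared across the package."""


class ValidationError(ValueError):
    """An input value violates a precondition of an operation."""


class ParseError(ValueError):
    """A CSV/TSV input file is malformed; the message carries the row number."""


class UnknownFormatError(KeyError):
    """A plate-format name is not in the registry; the message lists valid names."""

    def __str__(self) -> str:  # KeyError quotes its arg by default
        return self.args[0] if self.args else ""


class NonPhysicalMeasurementError(ValidationError):
    """A filter-only permeability at or below the total permeability: the
    endothelium would contribute no resistance, so the series correction is
    undefined."""
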
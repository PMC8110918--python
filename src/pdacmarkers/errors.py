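"""Exception and warning types shared across the package."""


class PdacMarkersError(Exception):
    """Base class for all errors raised by pdacmarkers."""


class ParseError(PdacMarkersError):
    """A file could not be parsed (malformed cell, section or panel)."""


class DuplicateGeneError(ParseError):
    """Duplicate gene symbols where uniqueness is required."""

    def __init__(self, duplicates):
        self.duplicates = sorted(duplicates)
        super().__init__(f"duplicate gene symbols: {', '.join(self.duplicates)}")


class ScaleError(PdacMarkersError):
    """Operation applied to a matrix on the wrong scale (e.g. double log2)."""


class MissingGeneError(PdacMarkersError):
    """A required gene symbol is absent from the matrix."""


class DegenerateInputError(PdacMarkersError):
    """Zero-variance input where a variance-normalised statistic is undefined."""


class CatalogError(PdacMarkersError):
    """Invalid gene-set catalog (duplicate cell types, dangling parent, ...)."""


class ConfigError(PdacMarkersError):
    """Invalid simulation or run configuration; message lists offending fields."""


class MarkerWarning(UserWarning):
    """Non-fatal analysis warnings (dropped genes, degenerate genes, ...)."""
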
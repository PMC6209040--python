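"""Package exception hierarchy."""


class BamorcError(Exception):
    """Base class for all package errors."""


class InsufficientDataError(BamorcError, ValueError):
    """Too few observations to perform the requested computation."""


class MissingClassError(BamorcError, ValueError):
    """A corpus does not cover every required (amino acid, SS) class."""

    def __init__(self, missing):
        self.missing = tuple(missing)
        super().__init__(
            "corpus is missing records for classes: "
            + ", ".join(f"{k.amino_acid_class}-{k.secondary_structure}" for k in self.missing)
        )


class DegenerateClusterError(BamorcError, ValueError):
    """Clustering input collapses to a single point."""


class UndefinedQError(BamorcError, ValueError):
    """Q statistic undefined because both RMSDs are zero."""


class NoBivariateModelError(BamorcError, ValueError):
    """A bivariate covariance matrix was requested for a glycine class."""


class SingularMatrixError(BamorcError, ValueError):
    """Covariance matrix is singular and cannot be inverted."""


class PeakListParseError(BamorcError, ValueError):
    """A peak-list line could not be parsed."""


class FormatError(BamorcError, ValueError):
    """An input file does not follow the expected format."""


class ValidationError(BamorcError, ValueError):
    """Inconsistent user input (lengths, alphabets, shapes)."""
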
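"""Exception hierarchy for the ewsso package."""


class EwssoError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(EwssoError):
    """Invalid term/axiom/distribution/rubric configuration."""


class GenerationError(EwssoError):
    """Synthetic-data generation failed (e.g. infeasible truncation)."""


class DatasetParseError(EwssoError):
    """Malformed dataset file; carries the offending row number."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        super().__init__(message if row is None else f"row {row}: {message}")


class MappingError(EwssoError):
    """A dataset column is mapped to an unknown ontology class."""


class DataError(EwssoError):
    """Inconsistent patient data (duplicate ids, duplicate measurements)."""


class PatientNotFoundError(EwssoError, KeyError):
    """Queried patient id does not exist in the graph."""


class ScoreLookupError(EwssoError, KeyError):
    """Unknown early-warning-score label."""


class UnitError(EwssoError):
    """A measurement carries a unit the conversion registry cannot handle."""


class RubricCoverageError(EwssoError):
    """A value fell outside every band of a rubric parameter, or the band
    table itself fails the coverage/exclusivity validation."""
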
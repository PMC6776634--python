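"""Exception hierarchy shared across the pipeline stages."""


class RetinaMechError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(RetinaMechError, ValueError):
    """A physical or protocol parameter is out of its valid domain."""


class NoContactError(RetinaMechError):
    """Contact-point detection found no sustained load crossing."""


class InsufficientDataError(RetinaMechError):
    """Too few samples/periods/groups for the requested computation."""


class ScheduleConflictError(RetinaMechError):
    """Overlapping, mutually contradictory stimulation events."""


class TriggerConsistencyError(RetinaMechError):
    """Stimulation triggers are unpaired, inverted or out of range."""


class NoShadowError(RetinaMechError):
    """No non-saturating connected component of the required size."""


class AlignmentError(RetinaMechError):
    """Unit sets (or trial ids) of two stages do not match."""


class DegenerateOutcomeError(RetinaMechError):
    """Classifier target has a single class."""


class SchemaError(RetinaMechError):
    """An input file violates the documented schema."""


class DuplicateLocationError(RetinaMechError):
    """Two indentation traces claim the same scan coordinate."""
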
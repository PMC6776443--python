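"""Exception taxonomy for the ribofret pipeline."""


class RibofretError(Exception):
    """Base class for all ribofret errors."""


class ValidationError(RibofretError):
    """A domain object violates one of its invariants."""


class TraceFormatError(RibofretError):
    """A trace table is malformed (missing column, bad dtype, ...)."""


class MissingSidecarError(TraceFormatError):
    """The JSON metadata sidecar for a trace table is absent."""


class NonUniformGridError(TraceFormatError):
    """Per-trace time stamps do not form a constant-interval grid."""


class DuplicateRecordError(TraceFormatError):
    """A (trace_id, frame) pair occurs more than once."""


class FitError(RibofretError):
    """A model fit failed on every attempted start."""


class EmptyDatasetError(RibofretError):
    """An operation received a dataset with no usable traces/frames."""


class DegenerateDataError(RibofretError):
    """Zero-variance or otherwise degenerate input to a statistic."""
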
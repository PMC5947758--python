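"""Exception hierarchy shared across the toolkit."""


class MrPrepError(Exception):
    """Base class for all toolkit errors."""


class ParseError(MrPrepError):
    """A file could not be parsed; the message names the offending line."""


class FormatError(MrPrepError):
    """A record cannot be serialized in the requested format."""


class AlignmentError(MrPrepError):
    """Inconsistent alignment rows or alignment/model mismatch."""


class SpanError(MrPrepError):
    """An alignment has no match columns to derive a span from."""


class StructureError(MrPrepError):
    """A structure violates an assumption (missing CA, multiple chains...)."""


class GeometryError(MrPrepError):
    """Degenerate or inconsistent coordinate geometry."""


class CoreError(MrPrepError):
    """No usable common core across ensemble members."""


class AnnotationError(MrPrepError):
    """A required per-member annotation (e.g. r.m.s.d.) is missing."""


class PipelineStageError(MrPrepError):
    """Wraps a failure inside a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
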
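"""Exception hierarchy shared across the package."""


class DDEGKError(Exception):
    """Base class for all package-specific errors."""


class DuplicateNode(DDEGKError):
    pass


class MalformedRoot(DDEGKError):
    pass


class SpanMismatch(DDEGKError):
    pass


class DanglingReference(DDEGKError):
    pass


class MalformedLine(DDEGKError):
    pass


class CyclicEventReference(DDEGKError):
    pass


class DuplicateTag(DDEGKError):
    pass


class EmptySpan(DDEGKError):
    pass


class InvalidWidth(DDEGKError):
    pass


class BackendUnavailable(DDEGKError):
    pass


class TrainingDiverged(DDEGKError):
    pass


class UnknownNode(DDEGKError):
    pass


class ShapeMismatch(DDEGKError):
    pass


class ZeroVector(DDEGKError):
    pass


class TooManyAnchors(DDEGKError):
    pass


class EmptyInput(DDEGKError):
    pass


class InvalidK(DDEGKError):
    pass


class TooFewPoints(DDEGKError):
    pass


class SchemaError(DDEGKError):
    pass


class ConfigError(DDEGKError):
    pass
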
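"""Exception hierarchy."""


class ShapeCompleteError(Exception):
    """Base class for all package errors."""


class MeshFormatError(ShapeCompleteError):
    """Malformed mesh file or invalid mesh geometry (e.g. out-of-range face index)."""


class TopologyError(ShapeCompleteError):
    """Operation requires meshes sharing one topology and they do not."""


class DegenerateFrameError(ShapeCompleteError):
    """Landmarks cannot define a full anatomical coordinate frame."""


class AlignmentError(ShapeCompleteError):
    """Rigid registration failed to produce a usable alignment."""


class ModelIntegrityError(ShapeCompleteError):
    """A persisted shape model failed its integrity or version check."""


class ValidationError(ShapeCompleteError):
    """Invalid configuration or arguments, detected before any compute."""
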
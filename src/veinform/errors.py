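"""Exception hierarchy shared across the package."""


class VeinformError(Exception):
    """Base class for all package-specific errors."""


class EmbeddingError(VeinformError):
    """The input is not a valid planar embedding (e.g. crossing edges)."""


class ConnectivityError(VeinformError):
    """The underlying graph is not connected."""


class GeometryError(VeinformError):
    """A geometric operation produced or met degenerate geometry."""


class PreconditionError(VeinformError):
    """An operation's documented precondition is violated."""


class AlignmentError(VeinformError):
    """Two per-edge records do not cover the same edge id set."""


class VectorizationError(VeinformError):
    """An image could not be turned into a network."""


class CodecError(VeinformError):
    """Main-path image encoding or decoding failed."""


class ReconstructionError(VeinformError):
    """A force geometry could not be rebuilt from a decoded main path."""


class TrainingError(VeinformError):
    """Model training diverged or received invalid data."""


class ExportError(VeinformError):
    """Geometry export (SVG/STL) failed."""


class RepairError(VeinformError):
    """A T-to-Y joint repair could not be applied without a collision."""


class SpecError(VeinformError):
    """A synthetic wing specification is internally inconsistent."""
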
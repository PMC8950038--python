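"""Exception types shared across the package."""


class NotFound(FileNotFoundError):
    """A required input file or manifest entry does not exist."""


class UnsupportedFormat(ValueError):
    """The file is readable but not in a format this tool accepts."""


class IOFailure(OSError):
    """Writing an output file failed (missing directory, permissions, ...)."""


class ShapeError(ValueError):
    """Array shapes are inconsistent with the operation's contract."""


class MissingClass(ValueError):
    """A label collection lacks one of the three semantic classes."""


class EmptyDataset(ValueError):
    """A training or validation set contains no samples."""


class DivergenceError(RuntimeError):
    """Training produced a non-finite loss."""

    def __init__(self, epoch: int, message: str | None = None):
        self.epoch = epoch
        super().__init__(message or f"non-finite loss at epoch {epoch}")


class InsufficientPairs(ValueError):
    """Too few matched object pairs for a correlation estimate."""


class UnknownLayer(KeyError):
    """Requested layer or gate name is not present in the model graph."""


class ManifestError(ValueError):
    """Prediction/ground-truth file sets cannot be paired up."""
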
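"""Exception hierarchy.

All package errors derive from :class:`DTIForgeError` so callers (and
the CLI) can distinguish input/contract problems from numerical
failures.
"""


class DTIForgeError(Exception):
    """Base class for all dtiforge errors."""


class ParseError(DTIForgeError):
    """Malformed input text (pair file, fingerprint, PSSM)."""


class EmptyDatasetError(DTIForgeError):
    """An interaction file contained no pairs."""


class SamplingInfeasibleError(DTIForgeError):
    """Fewer candidate negative pairs than requested."""


class UndefinedSparsityError(DTIForgeError):
    """Sparsity requested for a dataset with zero drugs or targets."""


class ShapeError(DTIForgeError):
    """Dimension mismatch between data and model configuration."""


class DivergenceError(DTIForgeError):
    """Training produced a non-finite loss."""

    def __init__(self, epoch: int, message: str | None = None):
        self.epoch = epoch
        super().__init__(message or f"non-finite loss at epoch {epoch}")


class MetricUndefinedError(DTIForgeError):
    """A metric's denominator is zero (e.g. AUC on a single class)."""


class WrongFingerprintTypeError(DTIForgeError):
    """Decoded fingerprint is not the 881-bit PubChem substructure key."""
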
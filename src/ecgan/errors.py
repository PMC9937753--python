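"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: :class:`ConfigError` -> 2,
:class:`DataError` -> 3, :class:`DivergenceError` -> 4.
"""


class EcganError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(EcganError, ValueError):
    """Invalid parameter, unsupported option, or inconsistent model config."""


class DataError(EcganError, ValueError):
    """Problems with the data itself (shapes, degenerate content, empty sets)."""


class ShapeError(DataError):
    """Array lengths or batch sizes do not line up."""


class DegenerateFragmentError(DataError):
    """A fragment is constant (max == min) and cannot be min-max normalized."""


class DegenerateInputError(DataError):
    """An input carries no energy where the operation needs some (all-zero signal)."""


class UnsupportedNoiseKindError(ConfigError):
    """Noise kind is not one of BW, MA, EM."""


class ChannelNotFoundError(DataError):
    """Requested channel name is absent from a WFDB record."""


class EmptyDatasetError(DataError):
    """Operation requires at least one fragment/batch but got none."""


class DivergenceError(EcganError, RuntimeError):
    """Training produced a non-finite loss."""

    def __init__(self, epoch: int, message: str | None = None):
        self.epoch = epoch
        super().__init__(message or f"non-finite loss at epoch {epoch}")
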
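"""Exception types shared across the package."""


class AesurvError(Exception):
    """Base class for package errors."""


class ConfigurationError(AesurvError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class ParseError(AesurvError, ValueError):
    """A malformed input table (duplicate ids, ragged rows, non-numeric cells)."""


class AlignmentError(AesurvError, ValueError):
    """Sample sets that cannot be aligned (e.g. empty intersection)."""


class ContractError(AesurvError, ValueError):
    """A violated call contract (shape mismatch, missing features, bad domain)."""


class DivergenceError(AesurvError, RuntimeError):
    """Non-finite loss encountered during training; carries the epoch."""

    def __init__(self, epoch: int, message: str | None = None):
        self.epoch = epoch
        super().__init__(message or f"training diverged (non-finite loss) at epoch {epoch}")
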
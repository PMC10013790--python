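"""Exception types shared across the pipeline."""


class WheatsegError(Exception):
    """Base class for all package errors."""


class InputError(WheatsegError, ValueError):
    """An input (file, directory, array, manifest) is missing or malformed."""


class CapacityError(WheatsegError, ValueError):
    """A request exceeds what the input can supply (e.g. too few eligible frames)."""


class PlacementError(WheatsegError, RuntimeError):
    """No valid placement was found within the attempt budget."""


class AugmentationError(WheatsegError, RuntimeError):
    """A geometric augmentation degenerated (e.g. emptied a footprint) after retries."""


class ShapeError(WheatsegError, ValueError):
    """Array shapes violate a contract (e.g. input size not divisible by the model stride)."""


class ConfigError(WheatsegError, ValueError):
    """A run configuration is incomplete or inconsistent."""


class DivergenceError(WheatsegError, RuntimeError):
    """Training produced a non-finite loss."""
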
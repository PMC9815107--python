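"""Exception taxonomy shared across the package.

The CLI maps these onto exit codes (configuration → 2, data → 3,
runtime → 4), so library code should raise the most specific type.
"""


class MsfnetError(Exception):
    """Base class for package errors."""


class ValidationError(MsfnetError, ValueError):
    """An input value violates a documented precondition."""


class ConfigurationError(MsfnetError, ValueError):
    """A configuration object is internally inconsistent."""


class DataError(MsfnetError, ValueError):
    """A dataset, manifest or image file is unusable."""


class TrainingDivergedError(MsfnetError, RuntimeError):
    """The training loss became non-finite."""

    def __init__(self, epoch: int, loss: float):
        super().__init__(f"training diverged at epoch {epoch}: loss={loss}")
        self.epoch = epoch
        self.loss = loss
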
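"""Exception hierarchy shared across the package."""


class PathomsiError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(PathomsiError, ValueError):
    """A domain object violates one of its invariants."""


class UnsupportedDialectError(PathomsiError, ValueError):
    """A file uses a dialect the package deliberately does not read."""


class TooFewAnchorsError(ValidationError):
    """Fewer than three anchor pairs were supplied."""


class SingularConfigurationError(ValidationError):
    """Anchor points are collinear or the transform is singular."""


class MisregistrationError(PathomsiError):
    """All spots map outside the mask raster: the transform is likely wrong."""


class ConfigError(PathomsiError, ValueError):
    """A configuration value is out of range or inconsistent."""


class StageError(PathomsiError, RuntimeError):
    """A pipeline stage failed; carries the stage name and sample id."""

    def __init__(self, stage: str, message: str, sample_id: str | None = None):
        self.stage = stage
        self.sample_id = sample_id
        where = f"stage '{stage}'" + (f", sample '{sample_id}'" if sample_id else "")
        super().__init__(f"{where}: {message}")
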
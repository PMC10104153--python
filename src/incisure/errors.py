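"""Exception hierarchy shared across the package."""

from __future__ import annotations


class InvalidInputError(ValueError):
    """A scalar or structured input violates a precondition."""


class SegmentationError(RuntimeError):
    """Disc segmentation produced no usable foreground."""

    stage = "segmentation"


class MorphometryError(RuntimeError):
    """A morphometry stage failed; ``stage`` names the failing step."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


class ConfigError(ValueError):
    """Pipeline configuration is invalid; lists every offending key."""

    def __init__(self, problems: list[str]):
        super().__init__(
            "invalid configuration:\n" + "\n".join(f"  - {p}" for p in problems)
        )
        self.problems = list(problems)
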
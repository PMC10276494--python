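"""Task paradigm: a single rest / task / rest block design.

Defaults encode the study block: 30 s pre-task rest, 330 s of continuous
task execution, 10 s post-task rest; task onset therefore at t = 30 s on
the recording clock.
"""

from __future__ import annotations

from dataclasses import dataclass

import yaml

from .errors import ValidationError


@dataclass(frozen=True)
class TaskParadigm:
    rest_pre: float = 30.0
    task: float = 330.0
    rest_post: float = 10.0

    def __post_init__(self) -> None:
        for name in ("rest_pre", "task", "rest_post"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0 s")

    @property
    def onset(self) -> float:
        """Task onset time in seconds (equals the pre-task rest duration)."""
        return self.rest_pre

    @property
    def total(self) -> float:
        return self.rest_pre + self.task + self.rest_post


def load_paradigm(path=None) -> TaskParadigm:
    """Load a paradigm from YAML; ``None`` or omitted keys use the defaults."""
    if path is None:
        return TaskParadigm()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    allowed = {"rest_pre", "task", "rest_post"}
    unknown = set(data) - allowed
    if unknown:
        raise ValidationError(f"unknown paradigm keys: {sorted(unknown)}")
    return TaskParadigm(**{k: float(v) for k, v in data.items()})


def write_paradigm(path, paradigm: TaskParadigm) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {
                "rest_pre": paradigm.rest_pre,
                "task": paradigm.task,
                "rest_post": paradigm.rest_post,
            },
            fh,
        )
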
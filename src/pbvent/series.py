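"""Core breath-by-breath ventilation record shared by all modules."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError

VALID_LABELS = ("PB", "nPB", "unknown")


@dataclass
class BreathSeries:
    """An ordered breath-by-breath ventilation record.

    Parameters
    ----------
    subject_id:
        Identifier of the subject the recording belongs to.
    times:
        Time of each breath in seconds, strictly increasing, one per breath.
    ve:
        Minute ventilation (L/min) measured for each breath; all positive.
    label:
        Group label, one of ``"PB"``, ``"nPB"`` or ``"unknown"``.
    meta:
        Free-form extras (e.g. simulator ground truth); never serialized.
    """

    subject_id: str
    times: np.ndarray
    ve: np.ndarray
    label: str = "unknown"
    meta: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.ve = np.asarray(self.ve, dtype=float)
        if self.times.ndim != 1 or self.ve.ndim != 1:
            raise ParameterError("times and ve must be one-dimensional")
        if len(self.times) != len(self.ve):
            raise ParameterError(
                f"times and ve lengths differ: {len(self.times)} != {len(self.ve)}"
            )
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ParameterError("times must be strictly increasing")
        if np.any(self.ve <= 0):
            bad = int(np.flatnonzero(self.ve <= 0)[0])
            raise ParameterError(f"ve must be positive; first offending breath: {bad}")
        if self.label not in VALID_LABELS:
            raise ParameterError(
                f"label must be one of {VALID_LABELS}, got {self.label!r}"
            )

    def __len__(self) -> int:
        return len(self.ve)
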
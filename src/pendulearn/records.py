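"""Shared record types tying trajectories, states and torques to one block."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .pendulum import PendulumTrace, PivotTrajectory


@dataclass(frozen=True)
class Modality:
    """Feedback modality of one block: haptic rendering and weight support."""

    hr: bool
    ws: bool

    @property
    def name(self) -> str:
        return {
            (False, False): "Visual",
            (False, True): "SupportedVisual",
            (True, False): "VisuoHaptic",
            (True, True): "SupportedVisuoHaptic",
        }[(self.hr, self.ws)]


#: Modality of all test blocks (baseline, catch trials, retention, transfer).
TEST_MODALITY = Modality(hr=True, ws=False)


@dataclass
class BlockRecording:
    """One 30-s experimental block.

    ``torques`` holds the participant-generated joint torque series
    (n, 2: shoulder, elbow); ``score`` is filled once computed.
    """

    modality: Modality
    phase_label: str
    rod_length: float
    pivot: PivotTrajectory
    states: PendulumTrace
    torques: Optional[np.ndarray] = None
    score: Optional[float] = None
    block_index: Optional[int] = None
    training_position: Optional[int] = None

    def __post_init__(self) -> None:
        if len(self.pivot) != len(self.states):
            raise ValueError("pivot and state series must have equal length")
        if self.torques is not None:
            self.torques = np.asarray(self.torques, dtype=float)
            if self.torques.shape[0] != len(self.pivot):
                raise ValueError("torque series length mismatch")


@dataclass(frozen=True)
class OutcomeMetrics:
    """Per-block outcome metrics (one data point per block each)."""

    score: float
    phase_diff: Optional[float]
    var_y: float
    var_z: float
    effort: Optional[float]

    def __post_init__(self) -> None:
        for name in ("var_y", "var_z"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.effort is not None and self.effort < 0:
            raise ValueError("effort must be non-negative")
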
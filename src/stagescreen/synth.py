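"""Synthetic class-conditional skeleton motion sessions.

The clinical dataset behind this package's method (596 children, three
classes) is not publicly deposited, so every downstream component is
exercised on sessions drawn from a generative stand-in with the same
*structure*: per child, 11 variable-length stage sequences of 18-joint 3D
frames and a 3-class label.

The motion model is deliberately minimal — additive superposition of

* a fixed standing posture (18 x 3 template, metres),
* a smooth purposeful-motion trajectory: low-frequency sinusoidal sway of
  the whole body, standing in for walking the number pad and gesturing, and
* extraneous motion with two coupled components, both scaled by a single
  per-(class, stage) step scale ``extraneous_sigma``:

  - a per-joint Gaussian random walk (integrated noise, so the positional
    jitter is temporally coherent like fidgeting rather than white), and
  - episodic postural restlessness: a fixed crouch/slump displacement
    pattern (upper body dropping, knees bending forward) modulated by a
    smooth restlessness process in [0, 1], emulating the sitting-down /
    standing-up and slumping episodes restless children show.

Extraneous motion is the only class-discriminative signal: normal children
move little throughout, ADHD children fidget heavily in every stage, and
at-risk children start out indistinguishable from normal but lose focus
from the third wait/game pair onward, which is where their sigma schedule
steps up.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .data import (
    LABELS,
    N_JOINTS,
    STAGES,
    EARLY_STAGES,
    Label,
    StageId,
    StageRecording,
    SubjectSession,
)

__all__ = ["MotionParams", "default_params", "simulate_subject", "simulate_dataset"]

#: Standing posture template, metres, sensor frame (y up, origin at floor
#: under the pelvis).  Rough proportions of an 8-13-year-old child.
BASE_POSTURE = np.array(
    [
        [0.00, 0.85, 0.00],   # pelvis
        [0.00, 1.15, 0.00],   # spine_chest
        [0.00, 1.30, 0.00],   # neck
        [0.00, 1.42, 0.00],   # head
        [-0.16, 1.25, 0.00],  # shoulder_left
        [-0.22, 1.02, 0.00],  # elbow_left
        [-0.24, 0.80, 0.02],  # wrist_left
        [0.16, 1.25, 0.00],   # shoulder_right
        [0.22, 1.02, 0.00],   # elbow_right
        [0.24, 0.80, 0.02],   # wrist_right
        [-0.09, 0.82, 0.00],  # hip_left
        [-0.10, 0.45, 0.00],  # knee_left
        [-0.11, 0.08, 0.00],  # ankle_left
        [-0.11, 0.03, 0.10],  # foot_left
        [0.09, 0.82, 0.00],   # hip_right
        [0.10, 0.45, 0.00],   # knee_right
        [0.11, 0.08, 0.00],   # ankle_right
        [0.11, 0.03, 0.10],   # foot_right
    ]
)

#: Study-condition class sizes: normal / at-risk / ADHD.
DEFAULT_CLASS_COUNTS = (349, 181, 66)

# Extraneous-motion step scales (metres per frame at 30 Hz).
# Normal: barely-visible idle sway.  ADHD: strong fidgeting in every stage.
# At-risk: normal-level early, elevated from the 3rd wait/game pair on.
SIGMA_LOW = 0.0005
SIGMA_RISK_LATE = 0.020
SIGMA_HIGH = 0.025

#: Full-crouch displacement of each joint relative to standing (metres):
#: the upper body drops and comes forward, the knees bend forward.
SLUMP_PATTERN = np.array(
    [
        [0.00, -0.18, 0.02],   # pelvis
        [0.00, -0.28, 0.08],   # spine_chest
        [0.00, -0.33, 0.10],   # neck
        [0.00, -0.36, 0.12],   # head
        [-0.02, -0.30, 0.08],  # shoulder_left
        [-0.02, -0.24, 0.06],  # elbow_left
        [-0.02, -0.16, 0.05],  # wrist_left
        [0.02, -0.30, 0.08],   # shoulder_right
        [0.02, -0.24, 0.06],   # elbow_right
        [0.02, -0.16, 0.05],   # wrist_right
        [-0.01, -0.17, 0.02],  # hip_left
        [-0.01, -0.08, 0.12],  # knee_left
        [0.00, 0.00, 0.00],    # ankle_left
        [0.00, 0.00, 0.00],    # foot_left
        [0.01, -0.17, 0.02],   # hip_right
        [0.01, -0.08, 0.12],   # knee_right
        [0.00, 0.00, 0.00],    # ankle_right
        [0.00, 0.00, 0.00],    # foot_right
    ]
)

#: AR(1) memory of the restlessness process: ~50-frame (1.7 s) episodes.
_RESTLESS_AR = 0.98


def _default_sigma_schedule() -> dict[tuple[Label, StageId], float]:
    sched: dict[tuple[Label, StageId], float] = {}
    for stage in STAGES:
        sched[(Label.NORMAL, stage)] = SIGMA_LOW
        sched[(Label.ADHD, stage)] = SIGMA_HIGH
        early = stage is StageId.EXPLAIN or stage in EARLY_STAGES
        sched[(Label.ADHD_RISK, stage)] = SIGMA_LOW if early else SIGMA_RISK_LATE
    return sched


@dataclass(frozen=True)
class MotionParams:
    """Everything that determines a synthetic cohort."""

    base_posture: np.ndarray = field(
        default_factory=lambda: BASE_POSTURE.copy()
    )
    task_amplitude: float = 0.02  # metres of purposeful body sway
    #: scale of the episodic slump component (2.0 = a full sit-down at
    #: ADHD-level restlessness; 0 disables it, leaving pure random-walk
    #: jitter as the extraneous motion).
    fidget_depth: float = 2.0
    #: multiplier on the random-walk step scale relative to the (class,
    #: stage) schedule; < 1 makes extraneous motion predominantly postural
    #: (slump episodes) with a smaller Brownian component on top.
    jitter_scale: float = 0.3
    extraneous_sigma: Mapping[tuple[Label, StageId], float] = field(
        default_factory=_default_sigma_schedule
    )
    length_range: Mapping[StageId, tuple[int, int]] = field(
        default_factory=lambda: {s: (150, 450) for s in STAGES}
    )
    class_counts: tuple[int, int, int] = DEFAULT_CLASS_COUNTS
    seed: int = 0

    def __post_init__(self) -> None:
        if np.asarray(self.base_posture).shape != (N_JOINTS, 3):
            raise ValueError("base_posture must be (18, 3)")
        if self.task_amplitude < 0:
            raise ValueError("task_amplitude must be >= 0")
        for key, sigma in self.extraneous_sigma.items():
            if sigma < 0:
                raise ValueError(f"extraneous_sigma{key} must be >= 0")
        for stage, (lo, hi) in self.length_range.items():
            if not 1 <= lo <= hi:
                raise ValueError(
                    f"length_range[{stage.name}] must satisfy 1 <= min <= max"
                )
        if any(c <= 0 for c in self.class_counts):
            raise ValueError("class_counts must be positive")

    def sigma(self, label: Label, stage: StageId) -> float:
        return float(self.extraneous_sigma[(label, stage)])


def default_params(**overrides) -> MotionParams:
    """The default study conditions: 349/181/66 subjects and the
    low / late-elevated / high extraneous-motion schedule per class."""
    return replace(MotionParams(), **overrides) if overrides else MotionParams()


def _stage_frames(
    params: MotionParams,
    label: Label,
    stage: StageId,
    rng: np.random.Generator,
) -> np.ndarray:
    lo, hi = params.length_range[stage]
    n = int(rng.integers(lo, hi + 1))
    t = np.arange(n, dtype=float)

    # Purposeful motion: two incommensurate low-frequency sways (periods of
    # a few seconds at 30 Hz), random phase per stage, applied to the whole
    # body so the limbs follow the pelvis.
    amp = params.task_amplitude
    phase = rng.uniform(0.0, 2.0 * np.pi, size=2)
    drift = np.zeros((n, 3))
    drift[:, 0] = amp * np.sin(2.0 * np.pi * t / 97.0 + phase[0])
    drift[:, 2] = amp * np.sin(2.0 * np.pi * t / 61.0 + phase[1])
    drift[:, 1] = 0.2 * amp * np.sin(2.0 * np.pi * t / 143.0 + phase[0])

    # Extraneous motion: per-joint random-walk jitter plus episodic slump,
    # both scaled by the (class, stage) step scale.
    sigma = params.sigma(label, stage)
    if sigma > 0.0:
        steps = rng.normal(0.0, sigma * params.jitter_scale,
                           size=(n, N_JOINTS, 3))
        jitter = steps.cumsum(axis=0)
        if params.fidget_depth > 0.0:
            # Smooth restlessness in [0, 1]: squashed stationary AR(1).
            a = _RESTLESS_AR
            eps = rng.normal(0.0, 1.0, size=n)
            u = np.empty(n)
            u[0] = rng.normal()
            for t_i in range(1, n):
                u[t_i] = a * u[t_i - 1] + np.sqrt(1.0 - a * a) * eps[t_i]
            occupancy = 1.0 / (1.0 + np.exp(-u / 1.2))
            depth = params.fidget_depth * sigma / SIGMA_HIGH
            jitter = jitter + (
                depth * occupancy[:, None, None] * SLUMP_PATTERN[None, :, :]
            )
    else:
        jitter = 0.0

    return params.base_posture[None, :, :] + drift[:, None, :] + jitter


def simulate_subject(
    params: MotionParams,
    label: Label,
    rng: np.random.Generator,
    subject_id: str | None = None,
) -> SubjectSession:
    """Draw one subject's 11-stage session; deterministic given ``rng`` state."""
    if label not in LABELS:
        raise ValueError(f"invalid class label {label!r}")
    stages = {
        stage: StageRecording(stage, _stage_frames(params, label, stage, rng))
        for stage in STAGES
    }
    if subject_id is None:
        subject_id = f"{label.value}-anon"
    return SubjectSession(subject_id, label, stages)


def simulate_dataset(params: MotionParams) -> list[SubjectSession]:
    """Draw the full cohort: ``class_counts`` subjects per class.

    Each subject gets an independent child stream of the cohort seed, so the
    cohort is reproducible and individual subjects do not depend on how many
    others were drawn before them.
    """
    total = sum(params.class_counts)
    streams = np.random.SeedSequence(params.seed).spawn(total)
    sessions: list[SubjectSession] = []
    k = 0
    for label, count in zip(LABELS, params.class_counts):
        for i in range(count):
            rng = np.random.default_rng(streams[k])
            k += 1
            sessions.append(
                simulate_subject(
                    params, label, rng, subject_id=f"{label.value}-{i:04d}"
                )
            )
    return sessions
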
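"""Domain types and I/O for multi-stage skeleton screening sessions.

A screening session is one child moving through 11 ordered segments of a
robot-led game: one explanation segment, then five (waiting, game) pairs.
Each segment ("stage") yields a variable-length sequence of skeleton frames,
one frame being the 3D positions of 18 body joints in metres, nominally
sampled at 30 Hz.  A session carries a 3-class clinical label
(normal / ADHD-risk / ADHD).

Because stage durations differ between children, the model consumes
fixed-size arrays built by zero-padding every sequence of a stage up to a
per-stage reference length (the longest observed sequence of that stage in
the training set).  Frames are flattened joint-major to 54 features
(joint0.x, joint0.y, joint0.z, joint1.x, ...).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum, IntEnum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "JOINT_NAMES",
    "N_JOINTS",
    "N_FEATURES",
    "Joint",
    "Frame",
    "StageId",
    "Label",
    "StageRecording",
    "SubjectSession",
    "ReferenceLengths",
    "PaddedStageBatch",
    "OverflowPolicy",
    "SessionFormatError",
    "read_sessions",
    "write_sessions",
    "sessions_to_long_dataframe",
    "write_sessions_csv",
    "compute_reference_lengths",
    "pad_sessions",
]

# Fixed 18-joint vocabulary.  The depth sensor natively tracks more joints;
# this package consumes a curated 18-joint subset.  The exact subset is a
# documented convention of this package: the axial chain plus symmetric
# left/right limb joints (4 + 2*7 = 18).
JOINT_NAMES: tuple[str, ...] = (
    "pelvis",
    "spine_chest",
    "neck",
    "head",
    "shoulder_left",
    "elbow_left",
    "wrist_left",
    "shoulder_right",
    "elbow_right",
    "wrist_right",
    "hip_left",
    "knee_left",
    "ankle_left",
    "foot_left",
    "hip_right",
    "knee_right",
    "ankle_right",
    "foot_right",
)

N_JOINTS = 18
N_FEATURES = N_JOINTS * 3  # joint-major flattening: j0.x j0.y j0.z j1.x ...

PELVIS_INDEX = 0


@dataclass(frozen=True)
class Joint:
    """One entry of the fixed 18-joint vocabulary."""

    index: int
    name: str

    def __post_init__(self) -> None:
        if not 0 <= self.index < N_JOINTS:
            raise ValueError(f"joint index {self.index} outside 0..17")
        if JOINT_NAMES[self.index] != self.name:
            raise ValueError(
                f"joint {self.index} is named {JOINT_NAMES[self.index]!r}, "
                f"got {self.name!r}"
            )


JOINTS: tuple[Joint, ...] = tuple(Joint(i, n) for i, n in enumerate(JOINT_NAMES))


class StageId(IntEnum):
    """The 11 ordered segments of a screening session."""

    EXPLAIN = 0
    WAIT1 = 1
    WAIT2 = 2
    WAIT3 = 3
    WAIT4 = 4
    WAIT5 = 5
    GAME1 = 6
    GAME2 = 7
    GAME3 = 8
    GAME4 = 9
    GAME5 = 10


STAGES: tuple[StageId, ...] = tuple(StageId)
N_STAGES = len(STAGES)

#: Wait/game pairs 1-2: before the attention-decay breakpoint seen in
#: at-risk children; pairs 3-5: after it.
EARLY_STAGES: tuple[StageId, ...] = (
    StageId.WAIT1,
    StageId.WAIT2,
    StageId.GAME1,
    StageId.GAME2,
)
LATE_STAGES: tuple[StageId, ...] = (
    StageId.WAIT3,
    StageId.WAIT4,
    StageId.WAIT5,
    StageId.GAME3,
    StageId.GAME4,
    StageId.GAME5,
)


class Label(Enum):
    """Clinical 3-class label assigned by clinician consensus."""

    NORMAL = "NORMAL"
    ADHD_RISK = "ADHD_RISK"
    ADHD = "ADHD"


LABELS: tuple[Label, ...] = (Label.NORMAL, Label.ADHD_RISK, Label.ADHD)
LABEL_INDEX: dict[Label, int] = {lab: i for i, lab in enumerate(LABELS)}


class OverflowPolicy(Enum):
    """What to do with a sequence longer than its stage's reference length."""

    ERROR = "error"
    TRUNCATE_TAIL = "truncate_tail"


class SessionFormatError(ValueError):
    """Raised when a session file or session object violates the dialect."""


@dataclass(frozen=True)
class Frame:
    """A single skeleton frame: 18 joints x 3 coordinates (metres)."""

    coords: np.ndarray  # (18, 3)
    timestamp_index: int = 0

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (N_JOINTS, 3):
            raise SessionFormatError(
                f"frame coords must have shape (18, 3), got {coords.shape}"
            )
        if not np.all(np.isfinite(coords)):
            raise SessionFormatError("frame contains non-finite coordinates")
        if self.timestamp_index < 0:
            raise SessionFormatError("timestamp_index must be >= 0")
        object.__setattr__(self, "coords", coords)


@dataclass
class StageRecording:
    """One stage's variable-length sequence of skeleton frames.

    Frames are stored as a dense ``(n_frames, 18, 3)`` array; timestamps are
    the frame indices 0..n_frames-1 unless explicitly provided.
    """

    stage: StageId
    coords: np.ndarray  # (n_frames, 18, 3)
    timestamps: np.ndarray | None = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 3 or coords.shape[1:] != (N_JOINTS, 3):
            raise SessionFormatError(
                f"stage {self.stage.name}: coords must be (n, 18, 3), "
                f"got {coords.shape}"
            )
        if coords.shape[0] < 1:
            raise SessionFormatError(f"stage {self.stage.name}: no frames")
        if not np.all(np.isfinite(coords)):
            raise SessionFormatError(
                f"stage {self.stage.name}: non-finite coordinates"
            )
        self.coords = coords
        if self.timestamps is None:
            self.timestamps = np.arange(coords.shape[0])
        else:
            ts = np.asarray(self.timestamps)
            if ts.shape != (coords.shape[0],):
                raise SessionFormatError(
                    f"stage {self.stage.name}: timestamps shape mismatch"
                )
            if np.any(np.diff(ts) <= 0):
                raise SessionFormatError(
                    f"stage {self.stage.name}: timestamps not strictly increasing"
                )
            self.timestamps = ts

    @property
    def n_frames(self) -> int:
        return int(self.coords.shape[0])

    def frame(self, i: int) -> Frame:
        return Frame(self.coords[i], int(self.timestamps[i]))

    def flat(self) -> np.ndarray:
        """Joint-major flattened view, shape (n_frames, 54)."""
        return self.coords.reshape(self.n_frames, N_FEATURES)


@dataclass
class SubjectSession:
    """One child's complete 11-stage session plus clinical label."""

    subject_id: str
    label: Label
    stages: dict[StageId, StageRecording]

    def __post_init__(self) -> None:
        missing = [s for s in STAGES if s not in self.stages]
        if missing:
            raise SessionFormatError(
                f"incomplete session {self.subject_id!r}: missing stage(s) "
                + ", ".join(s.name for s in missing)
            )
        extra = [s for s in self.stages if s not in STAGES]
        if extra:
            raise SessionFormatError(
                f"session {self.subject_id!r}: unknown stage(s) {extra}"
            )
        for sid, rec in self.stages.items():
            if rec.stage != sid:
                raise SessionFormatError(
                    f"session {self.subject_id!r}: recording under key "
                    f"{sid.name} claims stage {rec.stage.name}"
                )

    def stage_lengths(self) -> dict[StageId, int]:
        return {s: self.stages[s].n_frames for s in STAGES}


@dataclass(frozen=True)
class ReferenceLengths:
    """Per-stage padding targets: the longest training sequence per stage."""

    lengths: Mapping[StageId, int]

    def __post_init__(self) -> None:
        for s in STAGES:
            if s not in self.lengths:
                raise ValueError(f"missing reference length for {s.name}")
            if self.lengths[s] < 1:
                raise ValueError(f"reference length for {s.name} must be >= 1")

    def __getitem__(self, stage: StageId) -> int:
        return int(self.lengths[stage])


@dataclass
class PaddedStageBatch:
    """Model-ready fixed-size arrays: one (n, ref_len, 54) block per stage.

    ``true_lengths[stage][i]`` is the unpadded frame count of subject ``i``'s
    recording of ``stage``; entries beyond it are exactly zero.
    """

    arrays: dict[StageId, np.ndarray]
    true_lengths: dict[StageId, np.ndarray]
    subject_ids: list[str]
    labels: list[Label]

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def label_indices(self) -> np.ndarray:
        return np.array([LABEL_INDEX[l] for l in self.labels], dtype=np.int64)

    def reference_lengths(self) -> ReferenceLengths:
        return ReferenceLengths(
            {s: self.arrays[s].shape[1] for s in STAGES}
        )

    def subset(self, idx: Sequence[int]) -> "PaddedStageBatch":
        idx = np.asarray(idx)
        return PaddedStageBatch(
            arrays={s: self.arrays[s][idx] for s in STAGES},
            true_lengths={s: self.true_lengths[s][idx] for s in STAGES},
            subject_ids=[self.subject_ids[i] for i in idx],
            labels=[self.labels[i] for i in idx],
        )


# ---------------------------------------------------------------------------
# Serialization: JSON-lines session dialect
# ---------------------------------------------------------------------------

def _session_to_record(session: SubjectSession) -> dict:
    return {
        "subject_id": session.subject_id,
        "label": session.label.value,
        "stages": {
            s.name: session.stages[s].coords.tolist() for s in STAGES
        },
    }


def _session_from_record(rec: dict, line_no: int) -> SubjectSession:
    try:
        subject_id = rec["subject_id"]
        label = Label(rec["label"])
        raw_stages = rec["stages"]
    except (KeyError, ValueError) as exc:
        raise SessionFormatError(
            f"line {line_no}: malformed session record ({exc})"
        ) from exc
    stages: dict[StageId, StageRecording] = {}
    for name, frames in raw_stages.items():
        try:
            sid = StageId[name]
        except KeyError as exc:
            raise SessionFormatError(
                f"line {line_no}: subject {subject_id!r}: unknown stage {name!r}"
            ) from exc
        try:
            coords = np.asarray(frames, dtype=float)
        except (TypeError, ValueError) as exc:
            raise SessionFormatError(
                f"line {line_no}: subject {subject_id!r}, stage {name}: "
                f"malformed frames ({exc})"
            ) from exc
        try:
            stages[sid] = StageRecording(sid, coords)
        except SessionFormatError as exc:
            raise SessionFormatError(f"line {line_no}: {exc}") from exc
    try:
        return SubjectSession(subject_id, label, stages)
    except SessionFormatError as exc:
        raise SessionFormatError(f"line {line_no}: {exc}") from exc


def write_sessions(sessions: Iterable[SubjectSession], path) -> None:
    """Write sessions as JSON lines, one subject per line, full precision.

    Floats are serialized with ``repr`` semantics, so a read/write round trip
    reproduces coordinates bit-exactly.
    """
    with open(path, "w") as fh:
        for session in sessions:
            fh.write(json.dumps(_session_to_record(session)))
            fh.write("\n")


def read_sessions(path) -> list[SubjectSession]:
    """Read and validate a JSON-lines session file; stable order by id."""
    sessions: list[SubjectSession] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise SessionFormatError(
                    f"line {line_no}: invalid JSON ({exc.msg})"
                ) from exc
            sessions.append(_session_from_record(rec, line_no))
    seen: set[str] = set()
    for s in sessions:
        if s.subject_id in seen:
            raise SessionFormatError(f"duplicate subject_id {s.subject_id!r}")
        seen.add(s.subject_id)
    sessions.sort(key=lambda s: s.subject_id)
    return sessions


def sessions_to_long_dataframe(
    sessions: Iterable[SubjectSession],
) -> pd.DataFrame:
    """Long-format table: subject_id, label, stage, frame_idx, joint_idx, x, y, z."""
    rows = []
    for session in sessions:
        for sid in STAGES:
            rec = session.stages[sid]
            n = rec.n_frames
            frame_idx = np.repeat(np.arange(n), N_JOINTS)
            joint_idx = np.tile(np.arange(N_JOINTS), n)
            coords = rec.coords.reshape(-1, 3)
            rows.append(
                pd.DataFrame(
                    {
                        "subject_id": session.subject_id,
                        "label": session.label.value,
                        "stage": sid.name,
                        "frame_idx": frame_idx,
                        "joint_idx": joint_idx,
                        "x": coords[:, 0],
                        "y": coords[:, 1],
                        "z": coords[:, 2],
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def write_sessions_csv(sessions: Iterable[SubjectSession], path) -> None:
    sessions_to_long_dataframe(sessions).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Preprocessing: per-stage reference lengths and zero padding
# ---------------------------------------------------------------------------

def compute_reference_lengths(
    sessions: Sequence[SubjectSession],
) -> ReferenceLengths:
    """Longest observed frame count per stage over a training collection."""
    if len(sessions) == 0:
        raise ValueError("cannot compute reference lengths of an empty collection")
    return ReferenceLengths(
        {
            s: max(sess.stages[s].n_frames for sess in sessions)
            for s in STAGES
        }
    )


def pad_sessions(
    sessions: Sequence[SubjectSession],
    refs: ReferenceLengths,
    policy: OverflowPolicy = OverflowPolicy.ERROR,
    center: bool = False,
) -> PaddedStageBatch:
    """Zero-pad every stage sequence up to its reference length.

    Each frame is flattened joint-major to 54 features.  Sequences shorter
    than the reference are extended with all-zero frames; sequences longer
    than it are an error under ``OverflowPolicy.ERROR`` or keep only their
    first ``ref`` frames under ``OverflowPolicy.TRUNCATE_TAIL`` (needed at
    inference time on subjects unseen when the references were fixed).

    ``center=True`` subtracts each frame's pelvis position from all joints
    before flattening (off by default: the model is trained on raw sensor
    coordinates).
    """
    n = len(sessions)
    arrays: dict[StageId, np.ndarray] = {}
    true_lengths: dict[StageId, np.ndarray] = {}
    for sid in STAGES:
        ref = refs[sid]
        block = np.zeros((n, ref, N_FEATURES), dtype=float)
        lens = np.zeros(n, dtype=np.int64)
        for i, session in enumerate(sessions):
            rec = session.stages[sid]
            coords = rec.coords
            if center:
                coords = coords - coords[:, PELVIS_INDEX : PELVIS_INDEX + 1, :]
            length = rec.n_frames
            if length > ref:
                if policy is OverflowPolicy.ERROR:
                    raise ValueError(
                        f"subject {session.subject_id!r}, stage {sid.name}: "
                        f"sequence length {length} exceeds reference {ref} "
                        f"(policy ERROR)"
                    )
                length = ref
                coords = coords[:ref]
            block[i, :length] = coords.reshape(length, N_FEATURES)
            lens[i] = length
        arrays[sid] = block
        true_lengths[sid] = lens
    return PaddedStageBatch(
        arrays=arrays,
        true_lengths=true_lengths,
        subject_ids=[s.subject_id for s in sessions],
        labels=[s.label for s in sessions],
    )
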
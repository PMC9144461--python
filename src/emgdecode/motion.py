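"""Classifier decisions -> cumulative joint-angle trajectories -> MOT files.

Every 62.5 ms window decision selects a per-frame *advancement vector*: the
increment, in degrees, of each of the 21 hand-model joint coordinates that
the decided movement advances in one video frame.  Accumulating the vectors
from a zero posture builds the motion matrix; 80 identical decisions span a
full 5-s repetition, so an ideal movement is the 80-fold accumulation of its
own vector.

Hand close (HC) is special: its first 18 frames flex the fingers only (HC1)
and the remaining frames add the thumb (HC2).  A single counter tracks how
many HC1 frames have been consumed across the whole decision stream.

Output is the OpenSim motion text format (``inDegrees=yes``); the files load
directly as a motion in the OpenSim GUI against the 21-DoF hand model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dataio import MOVEMENTS

__all__ = ["JOINT_NAMES", "ADVANCEMENT_TABLE", "FRAME_DT", "HC1_FRAMES",
           "MotionMatrix", "advancement_vector", "build_motion_matrix",
           "ideal_motion", "write_mot", "read_mot"]

FRAME_DT = 0.0625          # seconds per decision window (250 / 4000 Hz)
HC1_FRAMES = 18            # HC frames before the thumb joins the close
IDEAL_FRAMES = 80          # decisions in one full 5-s repetition

JOINT_NAMES = (
    "MCP2_lateral", "MCP2_flex", "PIP_flex", "DIP_flex",
    "MCP2M_lateral", "MCP2M_flex", "MPIP_flex", "MDIP_flex",
    "RCP2M_lateral", "RCP2M_flex", "RPIP_flex", "RDIP_flex",
    "LCP2M_lateral", "LCP2M_flex", "LPIP_flex", "LDIP_flex",
    "thumb_abd", "thumb_flex", "TCP2M_lateral", "TCP2M_flex", "TCP2M2_flex",
)

# Per-frame joint-angle increments, degrees.  Index finger = MCP2/PIP/DIP,
# middle = MCP2M/MPIP/MDIP, ring = RCP2M/RPIP/RDIP, little = LCP2M/LPIP/LDIP,
# thumb = thumb_*/TCP2M*.  HC has two rows (see module docstring).
_F = 1.4516
ADVANCEMENT_TABLE: dict[str, tuple[float, ...]] = {
    "HC1": (-0.3225, _F, _F, _F, 0, _F, _F, _F, 0.0483, _F, _F, _F,
            0.3225, _F, _F, _F, 0, 0, 0, 0, 0),
    "HC2": (-0.3225, _F, _F, _F, 0, _F, _F, _F, 0.0483, _F, _F, _F,
            0.3225, _F, _F, _F, 0.14, 1.26, -0.4, 0.2, 0.84),
    "I_I": (-0.3225, _F, _F, _F, 0, 0, 0, 0, 0, 0, 0, 0,
            0, 0, 0, 0, 0, 0, 0, 0, 0),
    "I_M": (-0.3225, _F, _F, _F, 0, _F, _F, _F, 0, 0, 0, 0,
            0, 0, 0, 0, 0, 0, 0, 0, 0),
    "IMR": (-0.3225, _F, _F, _F, 0, _F, _F, _F, 0.0483, _F, _F, _F,
            0, 0, 0, 0, 0, 0, 0, 0, 0),
    "L_L": (0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0,
            0.3225, _F, _F, _F, 0, 0, 0, 0, 0),
    "M_M": (0, 0, 0, 0, 0, _F, _F, _F, 0, 0, 0, 0,
            0, 0, 0, 0, 0, 0, 0, 0, 0),
    "M_R": (0, 0, 0, 0, 0, _F, _F, _F, 0.0483, _F, _F, _F,
            0, 0, 0, 0, 0, 0, 0, 0, 0),
    "MRL": (0, 0, 0, 0, 0, _F, _F, _F, 0.0483, _F, _F, _F,
            0.3225, _F, _F, _F, 0, 0, 0, 0, 0),
    "R_L": (0, 0, 0, 0, 0, 0, 0, 0, 0.0483, _F, _F, _F,
            0.3225, _F, _F, _F, 0, 0, 0, 0, 0),
    "R_R": (0, 0, 0, 0, 0, 0, 0, 0, 0.0483, _F, _F, _F,
            0, 0, 0, 0, 0, 0, 0, 0, 0),
    "T_I": (0, 0.3625, 0.675, 0.75, 0, 0, 0, 0, 0, 0, 0, 0,
            0, 0, 0, 0, 0, 0.7875, -0.25, 0.2875, 0.1273),
    "T_L": (0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0,
            0, 0.0585, 0.95, 0.8812, 0.175, 1.125, -0.25, 0.4125, 0.1825),
    "T_M": (0, 0, 0, 0, -0.0412, 0.28, 0.875, 0.9875, 0, 0, 0, 0,
            0, 0, 0, 0, 0.1875, 0.575, -0.25, 0.3825, 0.325),
    "T_R": (0, 0, 0, 0, 0, 0, 0, 0, 0, 0.1691, 0.9875, 0.875,
            0, 0, 0, 0, 0.1812, 0.875, -0.25, 0.3678, 0.3125),
    "T_T": (0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0,
            0, 0, 0, 0, 0.14, 1.26, -0.4, 0.2, 0.84),
}


@dataclass
class MotionMatrix:
    """Cumulative joint angles, degrees; first row is the zero posture."""

    angles: np.ndarray               # (frames, 21)
    dt: float = FRAME_DT

    @property
    def n_frames(self) -> int:
        return self.angles.shape[0]

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt


def advancement_vector(class_label: int, hc_counter: int = 0) -> np.ndarray:
    """The 21-coordinate increment for one decision.

    Label 1 (HC) uses the finger-only HC1 row while ``hc_counter`` is below
    18 and the thumb-including HC2 row afterwards; every other label has a
    single row named by its movement abbreviation.
    """
    label = int(class_label)
    if not 1 <= label <= len(MOVEMENTS):
        raise KeyError(f"unknown class label: {class_label!r}")
    if label == 1:
        key = "HC1" if hc_counter < HC1_FRAMES else "HC2"
    else:
        key = MOVEMENTS[label - 1]
    return np.array(ADVANCEMENT_TABLE[key], dtype=float)


def build_motion_matrix(decisions, dt: float = FRAME_DT,
                        hc_counter: int = 0) -> MotionMatrix:
    """Accumulate advancement vectors over a decision stream.

    Starts at the zero posture; each decision appends the previous row plus
    its advancement vector.  The HC counter persists across the whole stream
    (it is not reset between separate runs of HC decisions); pass
    ``hc_counter`` to resume a partially consumed close.
    Misclassified streams are valid input by design.
    """
    decisions = [int(d) for d in decisions]
    rows = np.zeros((len(decisions) + 1, len(JOINT_NAMES)))
    count = hc_counter
    for i, d in enumerate(decisions):
        vec = advancement_vector(d, count)
        if d == 1 and count < HC1_FRAMES:
            count += 1
        rows[i + 1] = rows[i] + vec
    return MotionMatrix(angles=rows, dt=dt)


def ideal_motion(class_label: int,
                 n_frames: int = IDEAL_FRAMES) -> MotionMatrix:
    """The idealized motion: the class's own vector accumulated n_frames
    times (81 rows including the zero posture)."""
    return build_motion_matrix([int(class_label)] * n_frames)


def write_mot(m: MotionMatrix, name: str, path: str | Path,
              include_zero_row: bool = True) -> None:
    """Write an OpenSim motion (.mot) text file.

    Header: name line, ``version=1``, ``nRows``, ``nColumns=22``,
    ``inDegrees=yes``, ``endheader``; then a tab-separated ``time`` + 21
    joint-coordinate table.  Values round-trip exactly through
    :func:`read_mot`.
    """
    angles = m.angles if include_zero_row else m.angles[1:]
    time = (m.time if include_zero_row else m.time[1:])
    n_rows, n_joints = angles.shape
    lines = [
        name,
        "version=1",
        f"nRows={n_rows}",
        f"nColumns={n_joints + 1}",
        "inDegrees=yes",
        "endheader",
        "\t".join(("time",) + JOINT_NAMES),
    ]
    for t, row in zip(time, angles):
        lines.append("\t".join(f"{v:.17g}" for v in (t, *row)))
    Path(path).write_text("\n".join(lines) + "\n")


def read_mot(path: str | Path) -> tuple[str, list[str], np.ndarray]:
    """Parse a MOT file written by :func:`write_mot`.

    Returns ``(name, column names, data)`` with data shaped
    ``(nRows, nColumns)`` including the time column.
    """
    text = Path(path).read_text().splitlines()
    name = text[0]
    header: dict[str, str] = {}
    i = 1
    while i < len(text) and text[i].strip() != "endheader":
        if "=" in text[i]:
            k, v = text[i].split("=", 1)
            header[k.strip()] = v.strip()
        i += 1
    if i == len(text):
        raise ValueError(f"{path}: missing endheader")
    columns = text[i + 1].split("\t")
    data = np.array([[float(v) for v in line.split("\t")]
                     for line in text[i + 2:] if line.strip()])
    n_rows = int(header.get("nRows", len(data)))
    n_cols = int(header.get("nColumns", len(columns)))
    if data.shape != (n_rows, n_cols):
        raise ValueError(f"{path}: data shape {data.shape} does not match "
                         f"header ({n_rows}, {n_cols})")
    return name, columns, data
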
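"""Database layout, movement-label mapping, and labeled-matrix assembly.

The database tree is one directory per subject (``sub1`` ... ``sub8``), each
holding one headerless CSV per movement, named by the movement abbreviation
(``HC.csv``, ``I_I.csv``, ...).  A movement file has 8 float columns (the sEMG
channels) and, with the default acquisition protocol, 240,000 rows = 12
concatenated 5-s repetitions at 4 kHz.

A *labeled sample matrix* is the 9-column float array built from these files:
columns 1-8 are the channels, column 9 is the integer movement-class label
(1..15).  Per-subject matrices concatenate the 15 movements in label order;
the global matrix concatenates the 8 subjects, so a 15 -> 1 transition in the
label column marks a subject boundary.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

#: Movement abbreviations in class-label order (label = index + 1).
#: HC = closed hand; single letters = individual finger flexion
#: (T thumb, I index, M middle, R ring, L little); multi-letter names are
#: simultaneous flexions of the named fingers.
MOVEMENTS: tuple[str, ...] = (
    "HC", "I_I", "I_M", "IMR", "L_L", "M_M", "M_R", "MRL",
    "R_L", "R_R", "T_I", "T_L", "T_M", "T_R", "T_T",
)

N_CHANNELS = 8
N_COLUMNS = N_CHANNELS + 1  # 8 channels + class label

_LABEL_OF = {name.upper(): i + 1 for i, name in enumerate(MOVEMENTS)}


def label_for(name: str) -> int:
    """Class label (1..15) for a movement abbreviation or file name.

    Case-insensitive; a trailing ``.csv`` (any case) is ignored.
    """
    stem = name.strip()
    if stem.lower().endswith(".csv"):
        stem = stem[:-4]
    try:
        return _LABEL_OF[stem.upper()]
    except KeyError:
        raise KeyError(f"unknown movement name: {name!r}") from None


def abbreviation_for(label: int) -> str:
    """Movement abbreviation for a class label (1..15)."""
    if not 1 <= int(label) <= len(MOVEMENTS):
        raise KeyError(f"unknown class label: {label!r}")
    return MOVEMENTS[int(label) - 1]


def read_movement_csv(path: str | os.PathLike, label: int) -> np.ndarray:
    """Read one movement CSV and append its class label as column 9.

    Returns an ``(n, 9)`` float array in file row order.  An empty file yields
    a ``(0, 9)`` array.  Ragged or non-numeric rows raise ``ValueError``
    naming the first offending row index.
    """
    if not 1 <= int(label) <= len(MOVEMENTS):
        raise KeyError(f"unknown class label: {label!r}")
    path = Path(path)
    try:
        df = pd.read_csv(path, header=None, dtype=float)
    except pd.errors.EmptyDataError:
        return np.empty((0, N_COLUMNS))
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric cell ({exc})") from exc
    if df.isna().any().any():
        bad = int(np.flatnonzero(df.isna().any(axis=1).to_numpy())[0])
        raise ValueError(f"{path}: ragged or non-numeric row at index {bad}")
    if df.shape[1] != N_CHANNELS:
        raise ValueError(
            f"{path}: expected {N_CHANNELS} columns, found {df.shape[1]}"
        )
    out = np.empty((len(df), N_COLUMNS))
    out[:, :N_CHANNELS] = df.to_numpy(dtype=float)
    out[:, N_CHANNELS] = float(label)
    return out


def write_movement_csv(path: str | os.PathLike, data: np.ndarray) -> None:
    """Write raw channel samples (n x 8, label column excluded) as plain CSV."""
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[1] not in (N_CHANNELS, N_COLUMNS):
        raise ValueError("expected an (n, 8) or (n, 9) array")
    np.savetxt(path, data[:, :N_CHANNELS], fmt="%.6f", delimiter=",")


def assemble_subject(matrices: list[np.ndarray]) -> np.ndarray:
    """Concatenate one subject's movement matrices, ordered by class label."""
    if not matrices:
        raise ValueError("no matrices to assemble")
    for m in matrices:
        if m.ndim != 2 or m.shape[1] != N_COLUMNS:
            raise ValueError(
                f"all inputs must have {N_COLUMNS} columns, got shape {m.shape}"
            )
    keyed = sorted(matrices, key=lambda m: (m[0, N_CHANNELS] if len(m) else 0))
    return np.concatenate(keyed, axis=0) if keyed else np.empty((0, N_COLUMNS))


def assemble_global(subject_matrices: list[np.ndarray]) -> np.ndarray:
    """Concatenate per-subject matrices in subject order (1 -> 8).

    The subject boundary remains detectable as a 15 -> 1 transition in the
    label column.
    """
    if not subject_matrices:
        raise ValueError("no matrices to assemble")
    for m in subject_matrices:
        if m.ndim != 2 or m.shape[1] != N_COLUMNS:
            raise ValueError(
                f"all inputs must have {N_COLUMNS} columns, got shape {m.shape}"
            )
    return np.concatenate(subject_matrices, axis=0)


def load_subject_dir(path: str | os.PathLike) -> np.ndarray:
    """Load all movement CSVs in a subject directory into one labeled matrix."""
    path = Path(path)
    parts = []
    for name in MOVEMENTS:
        candidates = [p for p in path.iterdir()
                      if p.suffix.lower() == ".csv" and
                      p.stem.upper() == name.upper()]
        if candidates:
            parts.append(read_movement_csv(candidates[0], label_for(name)))
    if not parts:
        raise FileNotFoundError(f"{path}: no movement CSV files found")
    return assemble_subject(parts)


def load_database(root: str | os.PathLike) -> tuple[list[np.ndarray], np.ndarray]:
    """Load a database tree; returns (per-subject matrices, global matrix)."""
    root = Path(root)
    subdirs = sorted(
        (d for d in root.iterdir() if d.is_dir() and d.name.startswith("sub")),
        key=lambda d: int("".join(c for c in d.name if c.isdigit()) or 0),
    )
    if not subdirs:
        raise FileNotFoundError(f"{root}: no subject directories (sub*)")
    subjects = [load_subject_dir(d) for d in subdirs]
    return subjects, assemble_global(subjects)


def save_features(path: str | os.PathLike, X: np.ndarray, labels: np.ndarray,
                  names: list[str]) -> None:
    """Persist a feature matrix as tab-separated text with a header row."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if X.shape[0] != labels.shape[0]:
        raise ValueError("X and labels disagree in length")
    if X.shape[1] != len(names):
        raise ValueError("names do not match feature count")
    df = pd.DataFrame(X, columns=names)
    df["class"] = labels.astype(int)
    df.to_csv(path, sep="\t", index=False)


def load_features(path: str | os.PathLike) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Load a feature matrix written by :func:`save_features`."""
    df = pd.read_csv(path, sep="\t")
    if "class" not in df.columns:
        raise ValueError(f"{path}: missing 'class' column")
    labels = df.pop("class").to_numpy(dtype=int)
    return df.to_numpy(dtype=float), labels, list(df.columns)
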
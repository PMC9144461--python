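"""Synthetic 8-channel forearm sEMG database generator.

Emulates the acquisition protocol the decoding pipeline assumes: 8 subjects x
15 finger-flexion classes x 12 repetitions, each repetition 5 s at 4 kHz
(20,000 rows), 8 unlabeled float channels per CSV file, 12 repetitions
concatenated per movement file (240,000 rows with defaults).

Signal model
------------
Each channel is band-limited (20-450 Hz) zero-mean Gaussian noise whose RMS is
modulated by a deterministic trapezoidal activation envelope (rest, ramp,
hold, release), riding on a constant-RMS band-limited baseline.  Per-class
channel amplitudes come from a class x channel activation map derived from
which fingers each movement flexes; subjects differ by a multiplicative
log-normal gain jitter on that map, and repetitions differ by a log-normal
amplitude jitter plus timing jitter of the envelope segments.  All outputs
are pure functions of (config, profile, seed).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import signal as sps

from .dataio import MOVEMENTS, write_movement_csv

__all__ = [
    "ProtocolConfig", "SubjectProfile", "ArtifactSpec",
    "default_activation_map", "default_profile",
    "generate_repetition", "generate_movement", "generate_dataset",
    "inject_artifacts",
]


@dataclass(frozen=True)
class ProtocolConfig:
    """Acquisition-protocol dimensions and signal band.

    Defaults reproduce the study protocol: 8 subjects, 15 movement classes,
    12 repetitions of 5 s sampled at 4 kHz on 8 channels, analysed in
    250-sample windows, signal content restricted to 20-450 Hz.
    """

    n_subjects: int = 8
    n_classes: int = 15
    n_reps: int = 12
    duration: float = 5.0
    fs: float = 4000.0
    n_channels: int = 8
    window_len: int = 250
    band: tuple[float, float] = (20.0, 450.0)

    def __post_init__(self):
        rows = self.duration * self.fs
        if abs(rows - round(rows)) > 1e-9:
            raise ValueError("duration * fs must be an integer row count")
        if self.window_len < 1 or self.window_len > round(rows):
            raise ValueError("window_len must be in [1, duration * fs]")
        if not 1 <= self.n_classes <= len(MOVEMENTS):
            raise ValueError(f"n_classes must be in [1, {len(MOVEMENTS)}]")
        lo, hi = self.band
        if not 0 < lo < hi < self.fs / 2:
            raise ValueError("band must satisfy 0 < lo < hi < fs/2")

    @property
    def rows_per_repetition(self) -> int:
        return round(self.duration * self.fs)

    @property
    def rows_per_file(self) -> int:
        return self.n_reps * self.rows_per_repetition

    @property
    def total_rows(self) -> int:
        return self.n_subjects * self.n_classes * self.rows_per_file

    @property
    def windows_per_repetition(self) -> int:
        """Full + remainder windows covering one repetition."""
        n, w = self.rows_per_repetition, self.window_len
        return n // w + (1 if n % w else 0)


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject signal amplitudes.

    activation_map: (n_classes, n_channels) RMS amplitudes (arbitrary units)
    of the movement-evoked signal component per channel.
    baseline_noise: RMS of the always-present baseline component.
    gain_jitter:    sigma of the log-normal per-(class, channel) gain spread
                    that was applied when the map was drawn (recorded for the
                    manifest; the map already includes it).
    """

    activation_map: np.ndarray
    baseline_noise: float = 0.008
    gain_jitter: float = 0.15
    seed: int = 0

    def __post_init__(self):
        amap = np.asarray(self.activation_map, dtype=float)
        object.__setattr__(self, "activation_map", amap)
        if amap.ndim != 2:
            raise ValueError("activation_map must be 2-D (classes x channels)")
        if (amap < 0).any() or self.baseline_noise < 0:
            raise ValueError("amplitudes must be non-negative")
        for i in range(len(amap)):
            for j in range(i + 1, len(amap)):
                if np.allclose(amap[i], amap[j]):
                    raise ValueError(
                        f"activation_map rows {i} and {j} are identical; "
                        "classes must be distinguishable"
                    )


@dataclass(frozen=True)
class ArtifactSpec:
    """Row-level artifact injection: a Bernoulli(rate) subset of rows has one
    randomly chosen channel multiplied by ``scale``."""

    rate: float
    scale: float
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError("rate must be in [0, 1]")
        if self.scale <= 1.0:
            raise ValueError("scale must exceed 1")


# Channel pairs (0-based) picked up predominantly by each flexing finger.
# Neighbouring fingers share channels, which makes neighbouring movements
# genuinely confusable -- the property the classifier comparison relies on.
_FINGER_CHANNELS = {
    "T": (0, 1), "I": (1, 2), "M": (3, 4), "R": (4, 5), "L": (6, 7),
}
_CLASS_FINGERS = {
    "HC": "TIMRL", "I_I": "I", "I_M": "IM", "IMR": "IMR", "L_L": "L",
    "M_M": "M", "M_R": "MR", "MRL": "MRL", "R_L": "RL", "R_R": "R",
    "T_I": "TI", "T_L": "TL", "T_M": "TM", "T_R": "TR", "T_T": "T",
}

#: Trapezoidal activation phases as fractions of the repetition duration:
#: rest, ramp-up, hold, release (0.5 s / 1 s / 2.5 s / 1 s at 5 s).
ENVELOPE_FRACTIONS = (0.1, 0.2, 0.5, 0.2)

_PRIMARY_AMPLITUDE = 0.12      # RMS of one finger's contribution per channel
_REP_AMPLITUDE_JITTER = 0.25   # per-repetition log-normal sigma
_REP_TIMING_JITTER = 0.10      # relative jitter on envelope breakpoints


def default_activation_map(n_classes: int = 15,
                           n_channels: int = 8) -> np.ndarray:
    """Nominal class x channel RMS map from the finger-to-channel layout.

    Channels shared by several flexing fingers accumulate amplitude, so all
    15 rows are pairwise distinct.
    """
    amap = np.full((n_classes, n_channels), 0.01)
    for k in range(n_classes):
        for finger in _CLASS_FINGERS[MOVEMENTS[k]]:
            for ch in _FINGER_CHANNELS[finger]:
                if ch < n_channels:
                    amap[k, ch] += _PRIMARY_AMPLITUDE
    return amap


def default_profile(subject_seed: int, n_classes: int = 15,
                    n_channels: int = 8, baseline_noise: float = 0.008,
                    gain_jitter: float = 0.15) -> SubjectProfile:
    """Draw a subject profile: nominal map x log-normal per-cell gain."""
    rng = np.random.default_rng(subject_seed)
    base = default_activation_map(n_classes, n_channels)
    jitter = np.exp(rng.normal(0.0, gain_jitter, size=base.shape))
    return SubjectProfile(activation_map=base * jitter,
                          baseline_noise=baseline_noise,
                          gain_jitter=gain_jitter, seed=subject_seed)


def _bandlimited_noise(rng: np.random.Generator, n: int, n_channels: int,
                       band: tuple[float, float], fs: float) -> np.ndarray:
    """Unit-RMS zero-mean noise confined to ``band`` (zero-phase filtered)."""
    white = rng.standard_normal((n, n_channels))
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, white, axis=0)
    rms = np.sqrt(np.mean(x**2, axis=0))
    rms[rms == 0] = 1.0
    return x / rms


def _envelope(rng: np.random.Generator, n: int) -> np.ndarray:
    """Trapezoid over n samples with jittered segment boundaries."""
    f_rest, f_ramp, f_hold, f_rel = ENVELOPE_FRACTIONS
    j = rng.uniform(1 - _REP_TIMING_JITTER, 1 + _REP_TIMING_JITTER, size=3)
    t0 = f_rest * j[0]
    t1 = t0 + f_ramp * j[1]
    t2 = t1 + f_hold * j[2]
    t3 = min(t2 + f_rel, 1.0)
    t = np.linspace(0.0, 1.0, n, endpoint=False)
    env = np.interp(t, [0.0, t0, t1, t2, t3], [0.0, 0.0, 1.0, 1.0, 0.0])
    return env


def generate_repetition(profile: SubjectProfile, class_label: int,
                        config: ProtocolConfig, seed: int) -> np.ndarray:
    """One repetition of one movement: ``(duration*fs, n_channels)`` floats.

    Reproducible: the output is a pure function of the arguments.
    """
    if not 1 <= int(class_label) <= config.n_classes:
        raise KeyError(f"unknown class label: {class_label!r}")
    if profile.activation_map.shape != (config.n_classes, config.n_channels):
        raise ValueError("activation_map shape does not match config")
    rng = np.random.default_rng(seed)
    n = config.rows_per_repetition
    amp = profile.activation_map[int(class_label) - 1]
    # draw order is fixed so that the same seed always yields the same signal
    env = _envelope(rng, n)
    rep_gain = np.exp(rng.normal(0.0, _REP_AMPLITUDE_JITTER,
                                 size=config.n_channels))
    if profile.baseline_noise == 0 and not amp.any():
        return np.zeros((n, config.n_channels))
    baseline = _bandlimited_noise(rng, n, config.n_channels, config.band,
                                  config.fs) * profile.baseline_noise
    carrier = _bandlimited_noise(rng, n, config.n_channels, config.band,
                                 config.fs)
    return baseline + carrier * env[:, None] * (amp * rep_gain)[None, :]


def _rep_seed(master_seed: int, subject: int, label: int, rep: int) -> int:
    """Deterministic per-repetition seed below 2**31."""
    h = hashlib.sha256(
        f"{master_seed}:{subject}:{label}:{rep}".encode()
    ).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _subject_seed(master_seed: int, subject: int) -> int:
    return _rep_seed(master_seed, subject, 0, -1)


def generate_movement(profile: SubjectProfile, class_label: int,
                      config: ProtocolConfig, master_seed: int,
                      subject: int) -> np.ndarray:
    """All ``n_reps`` repetitions of one movement, concatenated."""
    reps = [
        generate_repetition(
            profile, class_label, config,
            _rep_seed(master_seed, subject, class_label, r))
        for r in range(config.n_reps)
    ]
    return np.concatenate(reps, axis=0)


def generate_dataset(config: ProtocolConfig, master_seed: int,
                     out_dir: str | Path, overwrite: bool = False,
                     artifacts: ArtifactSpec | None = None) -> dict:
    """Write the full database tree + YAML manifest; returns the manifest.

    Layout: ``out_dir/sub<i>/<ABBR>.csv`` (headerless 8-column CSV), one file
    per movement, ``n_reps`` concatenated repetitions per file.  The same
    master seed always produces a byte-identical tree.
    """
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise FileExistsError(f"{out_dir} is not empty (pass overwrite=True)")
    out_dir.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "master_seed": int(master_seed),
        "config": {
            "n_subjects": config.n_subjects, "n_classes": config.n_classes,
            "n_reps": config.n_reps, "duration": config.duration,
            "fs": config.fs, "n_channels": config.n_channels,
            "window_len": config.window_len, "band": list(config.band),
        },
        "subjects": [],
    }
    if artifacts is not None:
        manifest["artifacts"] = {"rate": artifacts.rate,
                                 "scale": artifacts.scale}
    for s in range(1, config.n_subjects + 1):
        sseed = _subject_seed(master_seed, s)
        profile = default_profile(sseed, config.n_classes, config.n_channels)
        subdir = out_dir / f"sub{s}"
        subdir.mkdir(exist_ok=True)
        files = {}
        for label in range(1, config.n_classes + 1):
            data = generate_movement(profile, label, config, master_seed, s)
            if artifacts is not None:
                aspec = ArtifactSpec(artifacts.rate, artifacts.scale,
                                     seed=_rep_seed(master_seed, s, label, -2))
                data, _ = inject_artifacts(data, aspec)
            fname = f"{MOVEMENTS[label - 1]}.csv"
            write_movement_csv(subdir / fname, data)
            files[fname] = int(data.shape[0])
        manifest["subjects"].append({
            "id": s, "seed": int(sseed),
            "baseline_noise": profile.baseline_noise,
            "gain_jitter": profile.gain_jitter,
            "files": files,
        })
    with open(out_dir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest


def inject_artifacts(recording: np.ndarray,
                     spec: ArtifactSpec) -> tuple[np.ndarray, np.ndarray]:
    """Multiply one random channel of a Bernoulli(rate) subset of rows.

    Returns ``(corrupted copy, boolean affected-row mask)``.  Rows outside the
    mask are bit-identical to the input.
    """
    recording = np.asarray(recording, dtype=float)
    if recording.size == 0:
        raise ValueError("recording is empty")
    rng = np.random.default_rng(spec.seed)
    n, c = recording.shape
    mask = rng.random(n) < spec.rate
    out = recording.copy()
    idx = np.flatnonzero(mask)
    if idx.size:
        channels = rng.integers(0, c, size=idx.size)
        out[idx, channels] *= spec.scale
    return out, mask
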
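"""Raw labeled matrix -> 97-column feature matrix.

Four stages: Mahalanobis/chi-square outlier elimination over the 8 channels,
non-overlapping 250-row windowing with a remainder window per movement block,
12 time-domain features per channel per window (96 features + class label),
and z-score normalization fitted on training data.

Feature definitions (window x of length N, thresholds eps_zc, eps_ssc, T):

====  ==========================================================
MAV   mean absolute value, (1/N) sum |x_i|
MSV   mean square value, (1/N) sum x_i^2
SSI   simple square integral, sum x_i^2
RMS   root mean square, sqrt(MSV)  (the "square mean")
VAR   zero-mean EMG variance, sum x_i^2 / (N - 1); 0 when N = 1
TMk   k-th absolute time moment, |(1/N) sum x_i^k|, k = 3, 4, 5
WL    waveform length, sum |x_{i+1} - x_i|
ZC    zero crossings: x_i * x_{i+1} < 0 and |x_i - x_{i+1}| >= eps_zc
MYOP  myopulse percentage ratio, (1/N) sum 1[|x_i| >= T]
SSC   slope sign changes: (x_i - x_{i-1})(x_i - x_{i+1}) > 0 and
      max(|x_i - x_{i-1}|, |x_i - x_{i+1}|) >= eps_ssc
====  ==========================================================

Note "mean square value" and "square mean" are distinct features here: MSV is
the mean of squares, RMS its square root.  VAR uses the zero-mean convention
standard in the EMG feature literature (the signal is band-passed, hence
zero-mean by construction), not a mean-subtracted variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .dataio import N_CHANNELS, abbreviation_for

__all__ = [
    "FeatureParams", "NormalizationModel", "OutlierReport",
    "FEATURE_NAMES", "feature_names",
    "mahalanobis_sq", "chi2_critical", "remove_outliers",
    "make_windows", "features12", "feature_matrix",
    "normalize_fit", "normalize_apply",
]

FEATURE_NAMES = ("MAV", "MSV", "SSI", "RMS", "VAR", "TM3", "TM4", "TM5",
                 "WL", "ZC", "MYOP", "SSC")


@dataclass(frozen=True)
class FeatureParams:
    """Amplitude thresholds for the crossing-count features.

    Defaults: 0 for ZC and SSC (pure sign tests); 0.016 for MYOP, about twice
    the synthetic generator's baseline RMS, so rest segments score near 0.
    All in the (arbitrary) amplitude units of the recordings.
    """

    zc_threshold: float = 0.0
    ssc_threshold: float = 0.0
    myop_threshold: float = 0.016

    def __post_init__(self):
        if min(self.zc_threshold, self.ssc_threshold,
               self.myop_threshold) < 0:
            raise ValueError("thresholds must be >= 0")


@dataclass
class NormalizationModel:
    """Per-feature mean/sd estimated on training data (sd ddof=1).

    Constant training features (sd below 1e-12) get sd substituted by 1, so
    they map to exactly 0.
    """

    mean: np.ndarray
    sd: np.ndarray


@dataclass
class OutlierReport:
    """Bookkeeping for the outlier stage; kept + removed == total, globally
    and within every per-movement / per-subject stratum."""

    total_rows: int
    kept_rows: int
    removed_rows: int
    threshold: float
    p_level: float
    per_movement: dict = field(default_factory=dict)
    per_subject: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "total_rows": self.total_rows,
            "kept_rows": self.kept_rows,
            "removed_rows": self.removed_rows,
            "threshold": float(self.threshold),
            "p_level": float(self.p_level),
            "per_movement": self.per_movement,
            "per_subject": self.per_subject,
        }


def mahalanobis_sq(x: np.ndarray, mean: np.ndarray,
                   inv_cov: np.ndarray) -> float:
    """Squared Mahalanobis distance (x - mean)' inv_cov (x - mean)."""
    x = np.asarray(x, dtype=float)
    mean = np.asarray(mean, dtype=float)
    inv_cov = np.asarray(inv_cov, dtype=float)
    if x.shape != mean.shape or inv_cov.shape != (x.size, x.size):
        raise ValueError("dimension mismatch")
    d = x - mean
    return float(d @ inv_cov @ d)


def chi2_critical(df: int, p: float) -> float:
    """Central chi-square quantile at cumulative probability p."""
    if not 0.0 < p < 1.0:
        raise ValueError("p must be in (0, 1)")
    return float(stats.chi2.ppf(p, df))


def remove_outliers(m: np.ndarray, p: float = 0.999, ridge: float = 1e-9,
                    subject_ids: np.ndarray | None = None,
                    ) -> tuple[np.ndarray, OutlierReport]:
    """Drop whole rows whose 8-channel Mahalanobis distance exceeds the
    chi-square critical value.

    Mean and covariance are computed once over *all* input rows (the stage
    runs on the assembled matrix before any train/test split; the induced
    leakage is a documented property of the replicated procedure, not fixed
    here).  The label column is excluded from the distance (df = 8).
    """
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] < 10:
        raise ValueError("need a 2-D matrix with at least 10 rows")
    X = m[:, :N_CHANNELS]
    labels = m[:, N_CHANNELS].astype(int) if m.shape[1] > N_CHANNELS else None

    mean = X.mean(axis=0)
    cov = np.cov(X, rowvar=False)
    cov = cov + (ridge * np.trace(cov) / X.shape[1]) * np.eye(X.shape[1])
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "channel covariance singular even after ridge regularization")
    y = np.linalg.solve(chol, (X - mean).T)
    d2 = np.sum(y * y, axis=0)

    thr = chi2_critical(X.shape[1], p)
    keep = d2 <= thr
    report = OutlierReport(
        total_rows=int(m.shape[0]),
        kept_rows=int(keep.sum()),
        removed_rows=int((~keep).sum()),
        threshold=thr, p_level=p,
    )
    if labels is not None:
        for lab in np.unique(labels):
            sel = labels == lab
            report.per_movement[abbreviation_for(int(lab))] = {
                "total": int(sel.sum()),
                "kept": int((keep & sel).sum()),
                "removed": int((~keep & sel).sum()),
            }
    if subject_ids is not None:
        subject_ids = np.asarray(subject_ids)
        for sid in np.unique(subject_ids):
            sel = subject_ids == sid
            report.per_subject[int(sid)] = {
                "total": int(sel.sum()),
                "kept": int((keep & sel).sum()),
                "removed": int((~keep & sel).sum()),
            }
    return m[keep], report


def make_windows(m: np.ndarray,
                 window_len: int = 250) -> list[tuple[np.ndarray, int]]:
    """Chop a labeled matrix into non-overlapping windows.

    Windows never span a change in the label column; the last window of each
    contiguous same-label block holds the remainder (1..window_len rows).
    """
    if window_len < 1:
        raise ValueError("window_len must be >= 1")
    m = np.asarray(m, dtype=float)
    if m.shape[0] == 0:
        return []
    labels = m[:, N_CHANNELS].astype(int)
    boundaries = np.flatnonzero(np.diff(labels) != 0) + 1
    out: list[tuple[np.ndarray, int]] = []
    for block in np.split(np.arange(m.shape[0]), boundaries):
        lab = int(labels[block[0]])
        for start in range(0, block.size, window_len):
            rows = block[start:start + window_len]
            out.append((m[rows[0]:rows[-1] + 1, :N_CHANNELS], lab))
    return out


def _features_multichannel(w: np.ndarray, params: FeatureParams) -> np.ndarray:
    """12 features per channel for a (rows, channels) window -> (channels, 12)."""
    n = w.shape[0]
    absw = np.abs(w)
    sq = w * w
    mav = absw.mean(axis=0)
    msv = sq.mean(axis=0)
    ssi = sq.sum(axis=0)
    rms = np.sqrt(msv)
    var = ssi / (n - 1) if n > 1 else np.zeros(w.shape[1])
    tm3 = np.abs((w ** 3).mean(axis=0))
    tm4 = np.abs((sq * sq).mean(axis=0))
    tm5 = np.abs((w ** 5).mean(axis=0))
    myop = (absw >= params.myop_threshold).mean(axis=0)
    if n > 1:
        dif = np.diff(w, axis=0)
        wl = np.abs(dif).sum(axis=0)
        zc = ((w[:-1] * w[1:] < 0) &
              (np.abs(dif) >= params.zc_threshold)).sum(axis=0)
    else:
        wl = np.zeros(w.shape[1])
        zc = np.zeros(w.shape[1])
    if n > 2:
        d1 = w[1:-1] - w[:-2]
        d2 = w[1:-1] - w[2:]
        ssc = ((d1 * d2 > 0) &
               (np.maximum(np.abs(d1), np.abs(d2)) >= params.ssc_threshold)
               ).sum(axis=0)
    else:
        ssc = np.zeros(w.shape[1])
    return np.column_stack([mav, msv, ssi, rms, var, tm3, tm4, tm5,
                            wl, zc, myop, ssc]).astype(float)


def features12(x: np.ndarray,
               params: FeatureParams | None = None) -> np.ndarray:
    """The 12 time-domain features of one channel's window, in the fixed
    order MAV, MSV, SSI, RMS, VAR, TM3, TM4, TM5, WL, ZC, MYOP, SSC."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty input")
    return _features_multichannel(x[:, None],
                                  params or FeatureParams())[0]


def feature_names(n_channels: int = N_CHANNELS) -> list[str]:
    """Channel-major feature names: ch1's 12 features, then ch2's, ..."""
    return [f"{f}_ch{k}" for k in range(1, n_channels + 1)
            for f in FEATURE_NAMES]


def feature_matrix(windows: list[tuple[np.ndarray, int]],
                   params: FeatureParams | None = None,
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Feature rows for a window sequence: (n_windows, 12 * n_channels) X and
    (n_windows,) integer labels, channel-major column order."""
    params = params or FeatureParams()
    if not windows:
        return np.empty((0, 12 * N_CHANNELS)), np.empty((0,), dtype=int)
    rows = [_features_multichannel(w, params).ravel() for w, _ in windows]
    labels = np.array([lab for _, lab in windows], dtype=int)
    return np.asarray(rows), labels


def normalize_fit(X: np.ndarray) -> NormalizationModel:
    """Estimate per-feature mean and sd (ddof=1) on training rows."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training rows")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd = np.where(sd < 1e-12, 1.0, sd)
    return NormalizationModel(mean=mean, sd=sd)


def normalize_apply(model: NormalizationModel, X: np.ndarray) -> np.ndarray:
    """Apply training statistics; never re-estimates on the given rows."""
    X = np.asarray(X, dtype=float)
    return (X - model.mean) / model.sd
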
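"""Glucotyping: spectral clustering of CGM windows into variability classes.

Overlapping 150-min windows (30-min step) of a regular-grid trace are reduced
to four summary features — mean, SD, range, max absolute rate of change per
hour — standardized, and clustered into three groups with spectral clustering
(radial-basis affinity, bandwidth set to the median pairwise distance).  The
clusters are labeled low / moderate / severe glucose-variability patterns by
ascending centroid window-SD, and each participant-assessment is summarized
as the fraction of its windows falling in each class.

The training pool is the run's own windows (self-trained); very large pools
are subsampled (seeded) before the spectral step and every window is then
classified by nearest centroid in standardized feature space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import SpectralClustering

from .cgm_io import GlucoseTrace
from .errors import DegenerateInputError, UndefinedResultError

WINDOW_MINUTES = 150
STEP_MINUTES = 30
N_CLASSES = 3
MAX_TRAINING_WINDOWS = 1200

FEATURE_NAMES = ("mean", "sd", "range", "max_rate_per_h")
_SD_FEATURE = 1  # index of the window-SD feature used for severity ordering


@dataclass(frozen=True)
class GlucoseWindow:
    """One fixed-length, gap-free window of a regular-grid trace."""

    participant_id: str
    week: int
    start_time: object
    values: np.ndarray
    features: np.ndarray  # (mean, sd, range, max |dG/dt| per hour)


def _transform_features(features: np.ndarray) -> np.ndarray:
    """log1p-compress the right-skewed spread features (sd, range, rate)."""
    out = np.asarray(features, dtype=float).copy()
    out[..., 1:] = np.log1p(out[..., 1:])
    return out


@dataclass
class GlucotypeModel:
    """Fitted spectral-clustering glucotype model.

    ``centroids`` are severity-ordered (low, moderate, severe) mean feature
    vectors in transformed+standardized space; ``scaler_mean``/``scaler_std``
    reproduce the standardization; ``sigma`` is the training RBF bandwidth.
    """

    centroids: np.ndarray            # (3, n_features), severity-ordered
    scaler_mean: np.ndarray
    scaler_std: np.ndarray
    sigma: float
    seed: int
    n_training_windows: int

    def standardize(self, features: np.ndarray) -> np.ndarray:
        return (_transform_features(features) - self.scaler_mean) / self.scaler_std

    def assign(self, windows: list[GlucoseWindow]) -> np.ndarray:
        """Severity index (0=low, 1=moderate, 2=severe) per window."""
        feats = self.standardize(np.array([w.features for w in windows]))
        d = np.linalg.norm(feats[:, None, :] - self.centroids[None, :, :], axis=2)
        return np.argmin(d, axis=1)


def window_features(values: np.ndarray, cadence_minutes: float) -> np.ndarray:
    rate = np.abs(np.diff(values)) / (cadence_minutes / 60.0)
    return np.array([
        float(np.mean(values)),
        float(np.std(values, ddof=1)),
        float(np.ptp(values)),
        float(np.max(rate)) if len(rate) else 0.0,
    ])


def window_trace(
    trace: GlucoseTrace,
    window_minutes: int = WINDOW_MINUTES,
    step_minutes: int = STEP_MINUTES,
) -> list[GlucoseWindow]:
    """Cut a regular-grid trace into overlapping gap-free windows.

    Windows are half-open spans of ``window_minutes``; any window overlapping
    a grid hole (missing readings after gap-aware resampling) is dropped.  A
    trace shorter than one window yields an empty list.
    """
    cad = trace.cadence_minutes
    pts_per_window = int(round(window_minutes / cad))
    step_pts_time = step_minutes * 60.0
    sec = trace.seconds
    windows: list[GlucoseWindow] = []
    starts = np.arange(0.0, sec[-1] - (window_minutes * 60.0) + cad * 60.0 * 0.5 + 1e-6,
                       step_pts_time)
    for s in starts:
        lo = int(np.searchsorted(sec, s - 1e-6))
        hi = int(np.searchsorted(sec, s + window_minutes * 60.0 - 1e-6))
        vals = trace.values[lo:hi]
        tsec = sec[lo:hi]
        if len(vals) != pts_per_window:
            continue  # window overlaps a gap
        if len(tsec) > 1 and not np.allclose(np.diff(tsec), cad * 60.0):
            continue
        windows.append(GlucoseWindow(
            participant_id=trace.participant_id, week=trace.week,
            start_time=trace.timestamps[lo], values=vals,
            features=window_features(vals, cad)))
    return windows


def fit_glucotypes(
    windows: list[GlucoseWindow],
    seed: int = 0,
    n_clusters: int = N_CLASSES,
    max_training_windows: int = MAX_TRAINING_WINDOWS,
) -> GlucotypeModel:
    """Fit the 3-class spectral glucotype model on a training pool.

    Spread features are log1p-compressed, then all features standardized;
    the affinity is exp(-d^2 / (2 sigma^2)) with
    sigma the median pairwise Euclidean distance.  Clusters are relabeled by
    ascending centroid window-SD so index 0/1/2 always means low/moderate/
    severe variability.  Deterministic given the seed.
    """
    feats = np.array([w.features for w in windows], dtype=float)
    if len(feats) < 30:
        raise DegenerateInputError("need >= 30 training windows")
    if len(np.unique(feats, axis=0)) < n_clusters:
        raise DegenerateInputError("need >= 3 distinct feature vectors")
    rng = np.random.default_rng(seed)
    if len(feats) > max_training_windows:
        sel = rng.choice(len(feats), size=max_training_windows, replace=False)
        feats = feats[np.sort(sel)]
    tf = _transform_features(feats)
    mean = tf.mean(axis=0)
    std = tf.std(axis=0)
    # a spread that is negligible relative to the feature's magnitude is
    # float noise, not signal: standardizing by it would amplify noise
    floor = 1e-8 * np.maximum(1.0, np.abs(mean))
    std = np.where(std <= floor, 1.0, std)
    z = (tf - mean) / std
    d = pdist(z)
    sigma = float(np.median(d))
    if sigma <= 0:
        raise DegenerateInputError("zero median pairwise distance")
    affinity = np.exp(-squareform(d) ** 2 / (2.0 * sigma ** 2))
    labels = SpectralClustering(
        n_clusters=n_clusters, affinity="precomputed",
        random_state=int(seed) % (2 ** 31), assign_labels="kmeans",
    ).fit_predict(affinity)
    centroids = np.array([z[labels == k].mean(axis=0) for k in range(n_clusters)])
    order = np.argsort(centroids[:, _SD_FEATURE])
    return GlucotypeModel(
        centroids=centroids[order], scaler_mean=mean, scaler_std=std,
        sigma=sigma, seed=int(seed), n_training_windows=len(feats))


def classify_fractions(
    model: GlucotypeModel, windows: list[GlucoseWindow]
) -> tuple[float, float, float]:
    """Fractions of one assessment's windows in (low, moderate, severe)."""
    if not windows:
        raise UndefinedResultError("no windows to classify")
    sev = model.assign(windows)
    counts = np.bincount(sev, minlength=N_CLASSES).astype(float)
    frac = counts / counts.sum()
    return (float(frac[0]), float(frac[1]), float(frac[2]))
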
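"""Helix tilt angle, toppled-state classification and replica stability.

The S-component of an ECF transporter sits in the membrane either in the
canonical orientation (helix 5 roughly parallel to the bilayer normal,
tilt around 30°) or toppled (helix 5 roughly in-plane, tilt between 75°
and 125°). This module computes the per-frame tilt of helix 5 against the
bilayer normal, applies the toppled band, and aggregates replicas into the
stable-toppled fraction with a binomial standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, List, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator

from .frames import Frame, Selection

__all__ = [
    "TiltSeries",
    "StabilitySummary",
    "helix_axis",
    "tilt_angle",
    "classify_toppled",
    "replica_stability",
    "stability_summary",
    "tilt_vs_coordinate",
    "ToppledStabilityClassifier",
]

TOPPLED_BAND = (75.0, 125.0)


@dataclass
class TiltSeries:
    """Tilt angle of helix 5 vs the bilayer normal over time, one replica."""

    replica_id: str
    times: np.ndarray  # ps
    angles: np.ndarray  # degrees, [0, 180]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.times.shape != self.angles.shape:
            raise ValueError("times and angles must have the same length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.angles.size and (self.angles.min() < 0 or self.angles.max() > 180):
            raise ValueError("angles must lie in [0, 180] degrees")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class StabilitySummary:
    """Per-condition replica statistic: fraction of stable-toppled replicas."""

    condition_label: str
    n_replicas: int
    n_stable: int
    stable_fraction: float
    sd: float
    per_replica_toppled_fraction: List[float]


def helix_axis(frame: Frame, helix_sel: Selection) -> np.ndarray:
    """Principal axis of a helix bead cloud, oriented N-terminus → C-terminus.

    The axis is the largest-variance eigenvector of the position covariance
    of the selected backbone particles, sign-fixed to point from the centroid
    of the N-terminal half (lower residue ids) toward the C-terminal half.
    Returns a unit 3-vector.
    """
    rows = helix_sel.rows(frame)
    if len(rows) < 2:
        raise ValueError(f"helix selection {helix_sel.name!r} has fewer than 2 particles")
    pos = frame.positions[rows]
    centered = pos - pos.mean(axis=0)
    cov = centered.T @ centered
    evals, evecs = np.linalg.eigh(cov)
    if evals[-1] <= 1e-12:
        raise ValueError("degenerate helix selection: zero-variance particle cloud")
    axis = evecs[:, -1]
    # orient from N-terminal half toward C-terminal half
    order = np.argsort(frame.residue_ids[rows], kind="stable")
    half = len(rows) // 2
    n_half = pos[order[:half]].mean(axis=0)
    c_half = pos[order[-(len(rows) - half):]].mean(axis=0)
    if np.dot(axis, c_half - n_half) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def _endpoint_axis(frame: Frame, helix_sel: Selection) -> np.ndarray:
    """End-to-end alternative axis: C-half centroid minus N-half centroid."""
    rows = helix_sel.rows(frame)
    if len(rows) < 2:
        raise ValueError(f"helix selection {helix_sel.name!r} has fewer than 2 particles")
    pos = frame.positions[rows]
    order = np.argsort(frame.residue_ids[rows], kind="stable")
    half = len(rows) // 2
    v = pos[order[-(len(rows) - half):]].mean(axis=0) - pos[order[:half]].mean(axis=0)
    norm = np.linalg.norm(v)
    if norm <= 1e-12:
        raise ValueError("degenerate helix selection: coincident endpoint centroids")
    return v / norm


def tilt_angle(axis: np.ndarray, normal: np.ndarray = (0.0, 0.0, 1.0)) -> float:
    """Angle (degrees, in [0, 180]) between a helix axis and the membrane normal.

    The angle is *not* folded to [0, 90]: an axis pointing along −z makes
    180° with the +z normal, which is what distinguishes a toppled-and-
    inverted helix from a canonical one.
    """
    a = np.asarray(axis, dtype=float)
    n = np.asarray(normal, dtype=float)
    na, nn = np.linalg.norm(a), np.linalg.norm(n)
    if na <= 0 or nn <= 0:
        raise ValueError("zero vector passed to tilt_angle")
    cosang = np.clip(np.dot(a, n) / (na * nn), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def classify_toppled(angle: float, band: Tuple[float, float] = TOPPLED_BAND) -> bool:
    """True iff the tilt angle lies in the toppled band (bounds inclusive)."""
    return bool(band[0] <= angle <= band[1])


def replica_stability(series: TiltSeries, band: Tuple[float, float] = TOPPLED_BAND,
                      stable_threshold: float = 0.5) -> Tuple[float, bool]:
    """Toppled time fraction of one replica and the stable-toppled call.

    A replica counts as stably toppled iff it spends strictly more than
    ``stable_threshold`` (default 50%) of its frames in the toppled band.
    Frames are weighted equally.
    """
    if len(series) == 0:
        raise ValueError(f"replica {series.replica_id!r}: empty tilt series")
    toppled = (series.angles >= band[0]) & (series.angles <= band[1])
    frac = float(toppled.mean())
    return frac, frac > stable_threshold


class ToppledStabilityClassifier(BaseEstimator):
    """Replica-stability analysis of the toppled S-component orientation.

    Fit on a list of per-replica tilt series; the estimator classifies each
    frame as toppled (tilt within ``band``, bounds inclusive), calls a
    replica stably toppled when its toppled time fraction strictly exceeds
    ``stable_threshold``, and reports the fraction of stable replicas with
    a binomial standard deviation ``sqrt(p(1-p)/n)``.

    Parameters
    ----------
    band : (low, high) degrees
        Toppled tilt band; default (75, 125).
    stable_threshold : float
        Strict time-fraction threshold for a stable-toppled replica (0.5).
    sd_scale : {"fraction", "count"}
        Scale of the reported binomial SD; "count" multiplies by n.

    Attributes
    ----------
    n_replicas_, n_stable_ : int
    stable_fraction_ : float
    sd_ : float
    per_replica_toppled_fraction_ : list of float
    summary_ : StabilitySummary
    """

    def __init__(self, band: Tuple[float, float] = TOPPLED_BAND,
                 stable_threshold: float = 0.5, sd_scale: str = "fraction") -> None:
        self.band = band
        self.stable_threshold = stable_threshold
        self.sd_scale = sd_scale

    def fit(self, replicas: Sequence[TiltSeries], y=None,
            condition_label: str = "") -> "ToppledStabilityClassifier":
        replicas = list(replicas)
        if not replicas:
            raise ValueError("need at least one replica")
        if self.sd_scale not in ("fraction", "count"):
            raise ValueError(f"sd_scale must be 'fraction' or 'count', got {self.sd_scale!r}")
        fracs, stable = [], []
        for series in replicas:
            f, s = replica_stability(series, band=self.band,
                                     stable_threshold=self.stable_threshold)
            fracs.append(f)
            stable.append(s)
        n = len(replicas)
        n_stable = int(sum(stable))
        p_hat = n_stable / n
        sd = float(np.sqrt(p_hat * (1.0 - p_hat) / n))
        if self.sd_scale == "count":
            sd *= n
        self.n_replicas_ = n
        self.n_stable_ = n_stable
        self.stable_fraction_ = p_hat
        self.sd_ = sd
        self.per_replica_toppled_fraction_ = fracs
        self.summary_ = StabilitySummary(condition_label, n, n_stable, p_hat, sd, fracs)
        return self

    def predict(self, angles: np.ndarray) -> np.ndarray:
        """Classify tilt angles (degrees) as toppled (True) or canonical."""
        a = np.asarray(angles, dtype=float)
        return (a >= self.band[0]) & (a <= self.band[1])


def stability_summary(replicas: Sequence[TiltSeries], label: str = "",
                      band: Tuple[float, float] = TOPPLED_BAND,
                      stable_threshold: float = 0.5,
                      sd_scale: str = "fraction") -> StabilitySummary:
    """Aggregate replicas into the stable-toppled bar statistic (binomial SD)."""
    est = ToppledStabilityClassifier(band=band, stable_threshold=stable_threshold,
                                     sd_scale=sd_scale)
    return est.fit(replicas, condition_label=label).summary_


def tilt_series_from_frames(frames: Iterable[Frame], helix_sel: Selection,
                            replica_id: str = "replica",
                            normal: np.ndarray = (0.0, 0.0, 1.0),
                            axis_method: str = "principal") -> TiltSeries:
    """Compute a tilt series from trajectory frames.

    ``axis_method`` chooses the principal-axis (default) or endpoint
    definition of the helix axis.
    """
    axis_fn = {"principal": helix_axis, "endpoints": _endpoint_axis}.get(axis_method)
    if axis_fn is None:
        raise ValueError(f"axis_method must be 'principal' or 'endpoints', got {axis_method!r}")
    times, angles = [], []
    for fr in frames:
        times.append(fr.time)
        angles.append(tilt_angle(axis_fn(fr, helix_sel), normal))
    return TiltSeries(replica_id=replica_id, times=np.asarray(times), angles=np.asarray(angles))


def tilt_vs_coordinate(frames: Iterable[Frame], helix_sel: Selection,
                       rc_fn: Callable[[Frame], float], bins: np.ndarray,
                       normal: np.ndarray = (0.0, 0.0, 1.0),
                       axis_method: str = "principal"):
    """Mean tilt angle ± SD binned along a reaction coordinate.

    Mirrors the tilt-vs-distance profile along a dissociation pathway: each
    frame contributes its helix tilt to the bin holding its reaction-
    coordinate value. Returns ``(bin_centers, mean, sd, count)`` where empty
    bins carry NaN mean/SD (missing, never zero).
    """
    bins = np.asarray(bins, dtype=float)
    if bins.ndim != 1 or len(bins) < 2:
        raise ValueError("bins must be a 1-D array of at least 2 edges")
    axis_fn = {"principal": helix_axis, "endpoints": _endpoint_axis}[axis_method]
    rcs, angles = [], []
    for fr in frames:
        rcs.append(rc_fn(fr))
        angles.append(tilt_angle(axis_fn(fr, helix_sel), normal))
    rcs = np.asarray(rcs)
    angles = np.asarray(angles)
    which = np.digitize(rcs, bins) - 1
    nb = len(bins) - 1
    mean = np.full(nb, np.nan)
    sd = np.full(nb, np.nan)
    count = np.zeros(nb, dtype=int)
    for b in range(nb):
        sel = which == b
        count[b] = int(sel.sum())
        if count[b]:
            mean[b] = angles[sel].mean()
            sd[b] = angles[sel].std(ddof=0)
    if count.sum() == 0:
        raise ValueError("no frames fall inside the reaction-coordinate bins")
    centers = 0.5 * (bins[:-1] + bins[1:])
    return centers, mean, sd, count
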
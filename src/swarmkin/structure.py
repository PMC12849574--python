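"""Swarm spatial structure: Gaussian fit, confidence ellipsoid, core partition.

The swarm is modelled as a single 3D Gaussian over all frame positions
of the swarming tracks in one replicate recording. The 90% confidence
ellipsoid is the Mahalanobis ball of squared radius equal to the
chi-squared(df=3) quantile at the confidence level; its semi-axes are
sqrt(chi2_crit * lambda_i) along the covariance eigenvectors. Frames
inside are the swarm *core*; a track is core when a configurable
fraction of its frames (default one half) is core. Swarm density is the
number of core tracks per ellipsoid volume.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DegenerateSwarmError
from .filtering import mean_track_speed
from .tracks import Track

__all__ = [
    "SwarmEllipsoid",
    "GroupSummary",
    "fit_gaussian",
    "chi2_critical",
    "mahalanobis_sq",
    "mahalanobis_core",
    "ellipsoid_volume",
    "fit_swarm_ellipsoid",
    "summarize_group",
    "summarize_replicates",
]

VOLUME_CONVENTIONS = ("ellipsoid", "axes_product", "semi_axes_product")


def fit_gaussian(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Maximum-likelihood single-Gaussian fit of n x 3 positions (cm).

    Equivalent to a one-component Gaussian mixture with full covariance:
    the sample mean and the ML covariance (divisor n). A relative jitter
    of 1e-9 * trace/3 is added to the diagonal when the scatter is close
    to singular.

    Raises
    ------
    DegenerateSwarmError
        For fewer than 4 points or a rank-deficient scatter.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise DegenerateSwarmError(f"expected n x 3 positions, got shape {pts.shape}")
    n = pts.shape[0]
    if n < 4:
        raise DegenerateSwarmError(f"need >= 4 points to fit the swarm Gaussian, got {n}")
    mean = pts.mean(axis=0)
    centred = pts - mean
    cov = centred.T @ centred / n
    cov = 0.5 * (cov + cov.T)
    eigvals = np.linalg.eigvalsh(cov)
    tr = np.trace(cov)
    if tr <= 0 or eigvals[0] <= 1e-12 * tr:
        jitter = 1e-9 * max(tr, 1e-30) / 3.0
        cov = cov + jitter * np.eye(3)
        eigvals = np.linalg.eigvalsh(cov)
        if eigvals[0] <= 0 or tr <= 0:
            raise DegenerateSwarmError("rank-deficient point scatter; swarm is degenerate")
    return mean, cov


def chi2_critical(confidence: float = 0.90, df: int = 3) -> float:
    """Chi-squared quantile used to scale the ellipsoid axes."""
    if not 0.0 < confidence < 1.0:
        raise ConfigError(f"confidence must be in (0, 1), got {confidence}")
    if df < 1:
        raise ConfigError(f"df must be >= 1, got {df}")
    return float(stats.chi2.ppf(confidence, df))


def mahalanobis_sq(points: np.ndarray, mean: np.ndarray, covariance: np.ndarray) -> np.ndarray:
    """Squared Mahalanobis distance of each point from the Gaussian mean."""
    cov = np.asarray(covariance, dtype=float)
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise DegenerateSwarmError("singular covariance in Mahalanobis distance") from exc
    diff = np.atleast_2d(points) - np.asarray(mean, dtype=float)
    sol = np.linalg.solve(L, diff.T)
    return np.einsum("ij,ij->j", sol, sol)


def mahalanobis_core(
    points: np.ndarray, mean: np.ndarray, covariance: np.ndarray, chi2_crit: float
) -> np.ndarray:
    """Boolean core mask: squared Mahalanobis distance <= chi2_crit."""
    return mahalanobis_sq(points, mean, covariance) <= chi2_crit


def ellipsoid_volume(
    covariance: np.ndarray, chi2_crit: float, convention: str = "ellipsoid"
) -> float:
    """Volume (cm^3) of the confidence ellipsoid with semi-axes sqrt(chi2 * lambda_i).

    Conventions: "ellipsoid" is the geometric volume (4/3) pi r1 r2 r3
    (the default); "axes_product" is the full-axes product (2r1)(2r2)(2r3);
    "semi_axes_product" is r1 r2 r3. All scale identically with the
    covariance, differing by a constant factor.
    """
    if convention not in VOLUME_CONVENTIONS:
        raise ConfigError(f"unknown volume convention {convention!r}")
    eigvals = np.linalg.eigvalsh(np.asarray(covariance, dtype=float))
    if np.any(eigvals <= 0):
        raise DegenerateSwarmError("covariance not positive definite")
    semi = np.sqrt(chi2_crit * eigvals)
    prod = float(np.prod(semi))
    if convention == "ellipsoid":
        return 4.0 / 3.0 * np.pi * prod
    if convention == "axes_product":
        return 8.0 * prod
    return prod


@dataclass(frozen=True)
class SwarmEllipsoid:
    """Fitted swarm Gaussian and its confidence ellipsoid."""

    mean: np.ndarray
    covariance: np.ndarray
    confidence: float
    chi2_crit: float
    semi_axes: np.ndarray  # sorted descending, cm
    volume: float  # cm^3, per `convention`
    convention: str

    def contains(self, points: np.ndarray) -> np.ndarray:
        return mahalanobis_core(points, self.mean, self.covariance, self.chi2_crit)

    def track_is_core(self, track: Track, track_core_fraction: float = 0.5) -> bool:
        """A track is core when >= the given fraction of its frames is core."""
        return bool(self.contains(track.xyz).mean() >= track_core_fraction)

    def to_dict(self) -> dict:
        return {
            "mean_cm": self.mean.tolist(),
            "covariance_cm2": self.covariance.tolist(),
            "confidence": self.confidence,
            "chi2_crit": self.chi2_crit,
            "semi_axes_cm": self.semi_axes.tolist(),
            "volume_cm3": self.volume,
            "convention": self.convention,
        }


def fit_swarm_ellipsoid(
    tracks: Sequence[Track],
    confidence: float = 0.90,
    convention: str = "ellipsoid",
) -> SwarmEllipsoid:
    """Fit the Gaussian to all frames of the given (filtered) tracks and
    build the confidence ellipsoid."""
    if not tracks:
        raise DegenerateSwarmError("no tracks to fit a swarm ellipsoid on")
    pts = np.vstack([tr.xyz for tr in tracks])
    mean, cov = fit_gaussian(pts)
    crit = chi2_critical(confidence, df=3)
    eigvals = np.linalg.eigvalsh(cov)
    semi = np.sort(np.sqrt(crit * eigvals))[::-1]
    vol = ellipsoid_volume(cov, crit, convention)
    return SwarmEllipsoid(mean, cov, confidence, crit, semi, vol, convention)


@dataclass(frozen=True)
class GroupSummary:
    """Replicate-level swarm summary: counts, volume, density, core speed."""

    group_code: int
    replicate_id: str
    n_core_tracks: int
    volume: float  # cm^3
    density: float  # tracks / cm^3
    mean_speed: float  # m/s over core tracks; nan when no core track

    def to_row(self) -> dict:
        return {
            "group_code": self.group_code,
            "replicate_id": self.replicate_id,
            "n_tracks": self.n_core_tracks,
            "volume_cm3": self.volume,
            "density_per_cm3": self.density,
            "speed_mps": self.mean_speed,
        }


def summarize_group(
    tracks: Sequence[Track],
    ellipsoid: SwarmEllipsoid,
    *,
    track_core_fraction: float = 0.5,
    frame_rate: float = 100.0,
    replicate_id: str = "",
    group_code: int | None = None,
) -> GroupSummary:
    """Count core tracks against the fitted ellipsoid and derive density
    (= core tracks / volume) and the mean core-track speed.

    With zero core tracks the density is 0 and the speed is NaN (flagged,
    not silently zero).
    """
    if ellipsoid.volume <= 0:
        raise DegenerateSwarmError("zero-volume ellipsoid")
    core = [tr for tr in tracks if ellipsoid.track_is_core(tr, track_core_fraction)]
    n = len(core)
    speed = float(np.mean([mean_track_speed(tr, frame_rate) for tr in core])) if n else float("nan")
    code = group_code
    if code is None:
        codes = {tr.group_code for tr in tracks if tr.group_code is not None}
        code = codes.pop() if len(codes) == 1 else -1
    return GroupSummary(code, replicate_id, n, ellipsoid.volume, n / ellipsoid.volume, speed)


def summarize_replicates(summaries: Sequence[GroupSummary]) -> pd.DataFrame:
    """Aggregate replicate-level summaries to group mean +/- SD.

    Mirrors the published per-group table: number of tracks, ellipsoid
    volume, density and in-ellipsoid speed, each with mean and SD over
    replicates. Densities are per-replicate densities averaged, not a
    ratio of group means.
    """
    rows = pd.DataFrame([s.to_row() for s in summaries])
    agg = rows.groupby("group_code")[
        ["n_tracks", "volume_cm3", "density_per_cm3", "speed_mps"]
    ].agg(["mean", "std"])
    agg.columns = [f"{c}_{s}" for c, s in agg.columns]
    return agg.reset_index()
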
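"""Synthetic swarm trajectory generator with ground truth.

Stands in for raw stereo-videography recordings: emits tabular 3D
tracks with the statistical structure the analysis pipeline assumes, so
every stage can be validated against known truth.

Motion model
------------
A swarming mosquito flies a smooth circular loop (repetitive flight
loops are the signature of swarm participation) whose centre is drawn
from a Gaussian around the swarm centre. Loop orientation is uniform
over the sphere, so pooled over many tracks the positional covariance
converges to the scenario covariance: the loop radius r satisfies
r^2/3 = lambda_min/2 and the centre covariance is Sigma - (r^2/3) I,
both positive definite by construction. The loop's angular rate is set
so the realized chord-length mean speed matches the per-track target
speed (within a fraction of a percent at 100 fps).

Noise (non-swarming) tracks violate exactly one filter each: "slow"
(mean speed below 0.50 m/s), "short" (flight time below 25 s) or
"outside" (entirely beyond the +/-100 cm X box).

All randomness flows through one seeded NumPy Generator (PCG64), so a
fixed seed reproduces recorded values bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .filtering import DEFAULT_WINDOW, FilterConfig, apply_filters, mean_track_speed
from .structure import chi2_critical, ellipsoid_volume
from .tracks import Track

__all__ = [
    "SwarmScenario",
    "GroundTruth",
    "StudyGroundTruth",
    "TABLE1_VOLUMES",
    "TABLE1_SPEEDS",
    "TABLE1_TRACK_COUNTS",
    "covariance_for_volume",
    "generate_track",
    "generate_replicate",
    "generate_study",
    "generate_speed_density_rows",
]

# Published per-group means used as generator defaults:
# ellipsoid volume (cm^3), core mean speed (m/s) and core track count
# for the five OSR groups 0..200 (male-only .. female-only).
TABLE1_VOLUMES = {0: 399.8, 50: 302.1, 100: 327.4, 150: 553.3, 200: 625.3}
TABLE1_SPEEDS = {0: 0.73, 50: 0.68, 100: 0.66, 150: 0.79, 200: 0.87}
TABLE1_SPEED_SD = {0: 0.02, 50: 0.05, 100: 0.04, 150: 0.09, 200: 0.05}
TABLE1_TRACK_COUNTS = {0: 20, 50: 26, 100: 27, 150: 12, 200: 15}

#: Fixed unit-determinant swarm shape: wider along X than vertically (Y),
#: intermediate along Z. Scaled isotropically to hit a target volume.
_SHAPE = np.diag(np.array([1.6, 0.7, 1.0]) / np.prod([1.6, 0.7, 1.0]) ** (1.0 / 3.0))

#: Lowest admissible per-track target speed for a swarming track; keeps a
#: margin above the 0.50 m/s filter.
_MIN_SWARM_SPEED = 0.55


@dataclass(frozen=True)
class SwarmScenario:
    """Generating parameters of one replicate recording."""

    group_code: int = 100
    n_swarming_tracks: int = 20
    spatial_mean: np.ndarray = field(default_factory=lambda: np.array([0.0, 80.0, 0.0]))
    spatial_covariance: np.ndarray = field(default_factory=lambda: 3.3 * np.eye(3))
    speed_mean: float = 0.70  # m/s
    speed_sd: float = 0.05
    track_duration_range: tuple[float, float] = (35.0, 60.0)
    n_noise_tracks: int = 10
    noise_speed_range: tuple[float, float] = (0.15, 0.45)
    frame_rate: float = 100.0
    window: tuple[float, float] = DEFAULT_WINDOW
    empirical_moments: bool = False

    def __post_init__(self) -> None:
        cov = np.asarray(self.spatial_covariance, float)
        object.__setattr__(self, "spatial_covariance", cov)
        object.__setattr__(self, "spatial_mean", np.asarray(self.spatial_mean, float))
        if np.any(np.linalg.eigvalsh(cov) <= 0):
            raise ConfigError("spatial_covariance must be positive definite")
        if self.speed_mean <= 0:
            raise ConfigError("speed_mean must be positive")
        if self.noise_speed_range[1] >= 0.50:
            raise ConfigError("noise speeds must stay below the 0.50 m/s swarming threshold")

    @property
    def analytic_volume(self) -> float:
        """Geometric volume of the 90% confidence ellipsoid of the true Gaussian."""
        return ellipsoid_volume(self.spatial_covariance, chi2_critical(0.90, 3))


@dataclass(frozen=True)
class GroundTruth:
    """Per-replicate truth table emitted alongside the generated tracks."""

    table: pd.DataFrame  # track_id, kind, group_code, replicate_id, target_speed, duration
    true_mean: np.ndarray
    true_covariance: np.ndarray
    analytic_volume: float
    scenario: SwarmScenario

    @property
    def swarming_ids(self) -> set[str]:
        return set(self.table.loc[self.table["kind"] == "swarming", "track_id"])


def covariance_for_volume(volume: float, confidence: float = 0.90) -> np.ndarray:
    """Covariance with the fixed swarm shape whose confidence ellipsoid has
    exactly the requested geometric volume (cm^3)."""
    crit = chi2_critical(confidence, 3)
    det_target = (3.0 * volume / (4.0 * np.pi)) ** 2 / crit**3
    return det_target ** (1.0 / 3.0) * _SHAPE


def _random_orthonormal_pair(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    u = rng.normal(size=3)
    u /= np.linalg.norm(u)
    w = rng.normal(size=3)
    v = w - (w @ u) * u
    v /= np.linalg.norm(v)
    return u, v


def _loop_track(
    rng: np.random.Generator,
    center: np.ndarray,
    radius: float,
    speed_mps: float,
    duration: float,
    frame_rate: float,
    t0: float,
    track_id: str,
    replicate_id: str,
    group_code: int | None,
) -> Track:
    dt = 1.0 / frame_rate
    n = int(round(duration * frame_rate)) + 1
    t = t0 + np.arange(n) * dt
    u, v = _random_orthonormal_pair(rng)
    omega = speed_mps * 100.0 / radius  # cm/s over cm
    # chord-vs-arc correction so realized finite-difference speed hits target
    half = 0.5 * omega * dt
    if half > 1e-12:
        omega = omega * half / np.sin(half) if np.sin(half) > 0 else omega
    phase = rng.uniform(0.0, 2.0 * np.pi)
    ang = omega * (t - t0) + phase
    xyz = center + radius * (np.cos(ang)[:, None] * u + np.sin(ang)[:, None] * v)
    return Track(track_id, t, xyz, replicate_id=replicate_id, group_code=group_code)


def generate_track(
    scenario: SwarmScenario,
    duration: float,
    seed: int | np.random.Generator,
    *,
    track_id: str = "t0",
    t0: float | None = None,
    target_speed: float | None = None,
) -> Track:
    """Generate one swarming loop track under the scenario.

    The realized chord-length mean speed matches the (possibly drawn)
    target speed to well within 2%.
    """
    if duration <= 0:
        raise ConfigError("duration must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eigvals = np.linalg.eigvalsh(scenario.spatial_covariance)
    radius = float(np.sqrt(1.5 * eigvals[0]))
    center_cov = scenario.spatial_covariance - (radius**2 / 3.0) * np.eye(3)
    center = rng.multivariate_normal(scenario.spatial_mean, center_cov)
    if target_speed is None:
        target_speed = max(
            float(rng.normal(scenario.speed_mean, scenario.speed_sd)), _MIN_SWARM_SPEED
        )
    if t0 is None:
        lo, hi = scenario.window
        t0 = rng.uniform(lo, max(hi - 1.5 * duration, lo))
    return _loop_track(
        rng,
        center,
        radius,
        target_speed,
        duration,
        scenario.frame_rate,
        t0,
        track_id,
        "",
        scenario.group_code,
    )


def _noise_track(
    rng: np.random.Generator, scenario: SwarmScenario, kind: str, track_id: str
) -> Track:
    lo, hi = scenario.window
    if kind == "slow":
        speed = rng.uniform(*scenario.noise_speed_range)
        duration = rng.uniform(30.0, 50.0)
        center = rng.multivariate_normal(scenario.spatial_mean, scenario.spatial_covariance)
        radius = 5.0
    elif kind == "short":
        speed = rng.uniform(0.55, 0.9)
        duration = rng.uniform(5.0, 20.0)
        center = rng.multivariate_normal(scenario.spatial_mean, scenario.spatial_covariance)
        radius = 3.0
    elif kind == "outside":
        speed = rng.uniform(0.55, 0.9)
        duration = rng.uniform(30.0, 50.0)
        center = rng.multivariate_normal(scenario.spatial_mean, scenario.spatial_covariance)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        center[0] = sign * (120.0 + abs(rng.normal(0, 10)))
        radius = 3.0
    else:
        raise ConfigError(f"unknown noise kind {kind!r}")
    t0 = rng.uniform(lo, max(hi - 1.5 * duration, lo))
    return _loop_track(
        rng, center, radius, speed, duration, scenario.frame_rate, t0, track_id, "",
        scenario.group_code,
    )


def _match_moments(tracks: list[Track], mean: np.ndarray, cov: np.ndarray) -> list[Track]:
    """Affinely adjust pooled positions so the pooled ML mean/covariance equal
    the targets exactly (exact-second-moment sampling), then rescale each
    track's time axis so its realized mean speed is restored.

    The time-rescale factor is clipped so the track keeps a flight time
    above 26 s and a mean speed above 0.52 m/s: positions (and hence the
    matched moments) are unaffected by retiming, so the filter guarantees
    survive even when the affine adjustment stretches a trajectory.
    """
    pts = np.vstack([tr.xyz for tr in tracks])
    m_hat = pts.mean(axis=0)
    c = pts - m_hat
    s_hat = c.T @ c / len(pts)

    def msqrt(S, inv=False):
        w, V = np.linalg.eigh(S)
        w = np.clip(w, 1e-12, None)
        p = -0.5 if inv else 0.5
        return (V * w**p) @ V.T

    A = msqrt(cov) @ msqrt(s_hat, inv=True)
    out = []
    for tr in tracks:
        v_before = mean_track_speed(tr)
        xyz = (tr.xyz - m_hat) @ A.T + mean
        moved = replace(tr, xyz=xyz)
        v_new = mean_track_speed(moved)
        kappa = v_new / v_before
        lo = 26.0 / tr.duration  # duration floor
        hi = max(v_new / 0.52, lo)  # speed floor
        kappa = float(np.clip(kappa, lo, hi))
        t = tr.t[0] + (tr.t - tr.t[0]) * kappa
        out.append(replace(moved, t=t))
    return out


def generate_replicate(
    scenario: SwarmScenario,
    seed: int | np.random.Generator,
    *,
    replicate_id: str = "r0",
    noise_kinds: Sequence[str] = ("slow", "short", "outside"),
    validate: bool = True,
) -> tuple[list[Track], GroundTruth]:
    """Generate one replicate: swarming tracks plus noise tracks, shuffled.

    Construction guarantees that every swarming track passes all four
    filters and every noise track fails exactly one; with
    ``validate=True`` this is asserted by running the filter pipeline.
    With ``scenario.empirical_moments`` the pooled swarming-frame
    moments are matched exactly to the scenario values (the analogue of
    sampling "without noise" for volumetric ground truth).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    swarm: list[Track] = []
    for i in range(scenario.n_swarming_tracks):
        duration = rng.uniform(*scenario.track_duration_range)
        tid = f"{replicate_id}_s{i:03d}"
        tr = generate_track(scenario, duration, rng, track_id=tid)
        tr = replace(tr, replicate_id=replicate_id)
        swarm.append(tr)
    if scenario.empirical_moments and scenario.n_swarming_tracks >= 2:
        swarm = _match_moments(swarm, scenario.spatial_mean, scenario.spatial_covariance)
    for tr in swarm:
        rows.append(
            {
                "track_id": tr.track_id,
                "kind": "swarming",
                "group_code": scenario.group_code,
                "replicate_id": replicate_id,
                "mean_speed_mps": mean_track_speed(tr),
                "duration_s": tr.duration,
            }
        )
    noise: list[Track] = []
    for i in range(scenario.n_noise_tracks):
        kind = noise_kinds[i % len(noise_kinds)]
        tid = f"{replicate_id}_n{i:03d}"
        tr = _noise_track(rng, scenario, kind, tid)
        tr = replace(tr, replicate_id=replicate_id)
        noise.append(tr)
        rows.append(
            {
                "track_id": tid,
                "kind": kind,
                "group_code": scenario.group_code,
                "replicate_id": replicate_id,
                "mean_speed_mps": mean_track_speed(tr),
                "duration_s": tr.duration,
            }
        )
    tracks = swarm + noise
    order = rng.permutation(len(tracks))
    tracks = [tracks[i] for i in order]
    truth = GroundTruth(
        table=pd.DataFrame(rows),
        true_mean=scenario.spatial_mean,
        true_covariance=scenario.spatial_covariance,
        analytic_volume=scenario.analytic_volume,
        scenario=scenario,
    )
    if validate:
        cfg = FilterConfig(time_window=scenario.window, frame_rate=scenario.frame_rate)
        kept = {tr.track_id for tr in apply_filters(tracks, cfg)}
        if kept != truth.swarming_ids:
            raise AssertionError(
                "generator contract violated: filter output does not equal the swarming set"
            )
    return tracks, truth


@dataclass(frozen=True)
class StudyGroundTruth:
    """Truth for a multi-group, multi-replicate synthetic study."""

    replicates: dict[tuple[int, str], GroundTruth]
    volume_law: tuple[float, float, float] | None  # (a, b, c) when volumes follow it
    volumes_by_group: dict[int, float]
    speeds_by_group: dict[int, float]

    def table(self) -> pd.DataFrame:
        return pd.concat([gt.table for gt in self.replicates.values()], ignore_index=True)


def generate_study(
    seed: int | np.random.Generator,
    *,
    osr_codes: Sequence[int] = (0, 50, 100, 150, 200),
    volume_law: tuple[float, float, float] | None = None,
    volumes_by_group: dict[int, float] | None = None,
    speeds_by_group: dict[int, float] | None = None,
    speed_sd_by_group: dict[int, float] | None = None,
    tracks_by_group: dict[int, int] | None = None,
    n_replicates: int = 3,
    replicate_noise_sd: float = 0.3,
    n_noise_tracks: int = 10,
    empirical_moments: bool = False,
    track_duration_range: tuple[float, float] | None = None,
) -> tuple[list[Track], StudyGroundTruth]:
    """Generate a full synthetic study: groups x replicates of recordings.

    Per-group ellipsoid volumes follow the quadratic law ``volume_law``
    when given, otherwise the published per-group means; replicate
    volumes get multiplicative lognormal noise of the given sd. Group
    speeds, speed sds and swarming-track counts default to the published
    per-group values. ``empirical_moments`` switches on exact-moment
    sampling (use with ``replicate_noise_sd=0`` for noise-free recovery
    experiments).
    """
    if len(osr_codes) < 2:
        raise ConfigError("a study needs >= 2 groups")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    vols = dict(volumes_by_group or TABLE1_VOLUMES)
    if volume_law is not None:
        a, b, c = volume_law
        vols = {x: a * x * x + b * x + c for x in osr_codes}
    speeds = dict(speeds_by_group or TABLE1_SPEEDS)
    speed_sds = dict(speed_sd_by_group or TABLE1_SPEED_SD)
    counts = dict(tracks_by_group or TABLE1_TRACK_COUNTS)
    all_tracks: list[Track] = []
    reps: dict[tuple[int, str], GroundTruth] = {}
    for code in osr_codes:
        for r in range(n_replicates):
            rep_id = f"g{code:03d}_r{r}"
            vol = vols[code]
            if replicate_noise_sd > 0:
                vol = vol * float(np.exp(rng.normal(0.0, replicate_noise_sd)))
            extra = {}
            if track_duration_range is not None:
                extra["track_duration_range"] = tuple(track_duration_range)
            scenario = SwarmScenario(
                group_code=code,
                n_swarming_tracks=counts.get(code, 20),
                spatial_covariance=covariance_for_volume(vol),
                speed_mean=speeds.get(code, 0.70),
                speed_sd=speed_sds.get(code, 0.05),
                n_noise_tracks=n_noise_tracks,
                empirical_moments=empirical_moments,
                **extra,
            )
            tracks, truth = generate_replicate(
                scenario, rng, replicate_id=rep_id, validate=False
            )
            all_tracks.extend(tracks)
            reps[(code, rep_id)] = truth
    return all_tracks, StudyGroundTruth(reps, volume_law, vols, speeds)


def generate_speed_density_rows(
    seed: int | np.random.Generator,
    *,
    slope: float = -1.5,
    intercept: float = 0.84,
    replicate_sd: float = 0.02,
    resid_sd: float = 0.03,
    n_rows: int = 60,
    n_replicates: int = 15,
    density_range: tuple[float, float] = (0.01, 0.12),
) -> pd.DataFrame:
    """Simulate replicate-level (density, mean speed) rows from a known
    random-intercept law, for mixed-model parameter-recovery checks."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rep = rng.integers(0, n_replicates, size=n_rows)
    offsets = rng.normal(0.0, replicate_sd, size=n_replicates)
    density = rng.uniform(*density_range, size=n_rows)
    speed = intercept + slope * density + offsets[rep] + rng.normal(0, resid_sd, size=n_rows)
    return pd.DataFrame(
        {"density": density, "mean_speed": speed, "replicate_id": [f"r{i}" for i in rep]}
    )
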
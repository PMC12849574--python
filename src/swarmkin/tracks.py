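"""Track data model and I/O.

A *track* is the full 3D flight trajectory of a single mosquito as
reconstructed by a stereo videography device (nominally 100 frames/s).
Positions live in a world frame whose origin is the swarm marker on the
ground: X normal to the sunset horizon, Y vertically up, Z parallel to
the horizon. Canonical units are centimetres for positions and metres
per second for speeds; conversions happen only at I/O.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, TrackDataError, TrackFormatError

__all__ = [
    "Frame",
    "Track",
    "OSRGroup",
    "RigidTransform",
    "DEFAULT_DIALECT",
    "read_tracks",
    "write_tracks",
    "tracks_to_frame",
    "to_world_frame",
]

#: Operational sex ratio (OSR) label <-> integer code, male-only through
#: female-only. Codes double as the regressor in the volume trend model.
OSR_CODES: Mapping[str, int] = {
    "male_only": 0,
    "male_biased": 50,
    "balanced": 100,
    "female_biased": 150,
    "female_only": 200,
}
_CODE_TO_LABEL = {v: k for k, v in OSR_CODES.items()}

#: Default column names for delimited track tables.
DEFAULT_DIALECT: Mapping[str, str] = {
    "track_id": "track_id",
    "time": "time_s",
    "x": "x_cm",
    "y": "y_cm",
    "z": "z_cm",
    "speed": "speed_mps",
    "replicate_id": "replicate_id",
    "group_code": "group_code",
}


class Frame(NamedTuple):
    """One detection: time (s since recording start) and position (cm, world frame)."""

    t: float
    x: float
    y: float
    z: float


@dataclass(frozen=True)
class OSRGroup:
    """An operational-sex-ratio treatment group.

    The study design releases 200 mosquitoes per group; ``n_males`` and
    ``n_females`` are configurable for synthetic runs.
    """

    label: str
    n_males: int = 0
    n_females: int = 0

    def __post_init__(self) -> None:
        if self.label not in OSR_CODES:
            raise ConfigError(
                f"unknown OSR label {self.label!r}; expected one of {sorted(OSR_CODES)}"
            )

    @property
    def code(self) -> int:
        return OSR_CODES[self.label]

    @classmethod
    def from_code(cls, code: int, n_males: int = 0, n_females: int = 0) -> "OSRGroup":
        if code not in _CODE_TO_LABEL:
            raise ConfigError(f"unknown OSR code {code}; expected one of {sorted(_CODE_TO_LABEL)}")
        return cls(_CODE_TO_LABEL[code], n_males, n_females)


@dataclass
class Track:
    """Ordered 3D trajectory of one mosquito.

    Attributes
    ----------
    track_id : str
        Opaque identifier, unique within a recording.
    t : ndarray, shape (n,)
        Strictly increasing timestamps in seconds.
    xyz : ndarray, shape (n, 3)
        Positions in cm in the world frame.
    speed : ndarray, shape (n,), optional
        Device-reported instantaneous speed in m/s; None if absent.
    replicate_id : str
        Recording / replicate identifier.
    group_code : int or None
        OSR group code (0/50/100/150/200) when known.
    """

    track_id: str
    t: np.ndarray
    xyz: np.ndarray
    speed: np.ndarray | None = None
    replicate_id: str = ""
    group_code: int | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.speed is not None:
            self.speed = np.asarray(self.speed, dtype=float)
        if self.t.ndim != 1 or self.xyz.shape != (self.t.size, 3):
            raise TrackDataError(
                f"track {self.track_id!r}: t has shape {self.t.shape}, xyz {self.xyz.shape}"
            )
        if self.t.size < 2:
            raise TrackDataError(f"track {self.track_id!r}: needs >= 2 frames, got {self.t.size}")
        if np.any(np.diff(self.t) <= 0):
            raise TrackDataError(f"track {self.track_id!r}: timestamps not strictly increasing")
        if self.t[0] < 0:
            raise TrackDataError(f"track {self.track_id!r}: negative timestamp")

    @property
    def n_frames(self) -> int:
        return int(self.t.size)

    @property
    def duration(self) -> float:
        """Last-minus-first timestamp in seconds."""
        return float(self.t[-1] - self.t[0])

    @property
    def flight_time(self) -> float:
        """Summed inter-frame time of retained frames, in seconds.

        Equals :attr:`duration` for gapless tracks; smaller when frames
        were dropped mid-track by filtering.
        """
        dt = np.diff(self.t)
        frame_dt = np.median(dt)
        return float(dt[dt <= 1.5 * frame_dt].sum() + 0.0)

    def frames(self) -> Iterator[Frame]:
        for ti, (x, y, z) in zip(self.t, self.xyz):
            yield Frame(float(ti), float(x), float(y), float(z))

    def with_mask(self, keep: np.ndarray) -> "Track | None":
        """Return a copy restricted to frames where ``keep`` is True, or
        None if fewer than 2 frames survive."""
        keep = np.asarray(keep, dtype=bool)
        if keep.sum() < 2:
            return None
        return replace(
            self,
            t=self.t[keep],
            xyz=self.xyz[keep],
            speed=None if self.speed is None else self.speed[keep],
        )


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion p -> R p + translation (cm)."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        tr = np.asarray(self.translation, dtype=float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", tr)
        if R.shape != (3, 3) or tr.shape != (3,):
            raise ConfigError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or not np.isclose(
            np.linalg.det(R), 1.0, atol=1e-8
        ):
            raise ConfigError("rotation must be orthonormal with determinant +1")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


def _unit_factor(unit: str) -> float:
    try:
        return {"cm": 1.0, "m": 100.0, "mm": 0.1}[unit]
    except KeyError:
        raise ConfigError(f"unknown position unit {unit!r}; expected cm, m or mm") from None


def read_tracks(
    path,
    dialect: Mapping[str, str] | None = None,
    *,
    position_unit: str = "cm",
    sep: str = ",",
) -> list[Track]:
    """Read a delimited track table into a list of :class:`Track`.

    Rows are grouped by track id and sorted by time within each track.
    Positions are normalised to cm. Optional columns (speed, replicate
    id, group code) are carried through when present.

    Raises
    ------
    TrackFormatError
        If a mandatory column (track id, time, x, y, z) is absent.
    TrackDataError
        If a track has duplicate timestamps.
    """
    cols = dict(DEFAULT_DIALECT)
    if dialect:
        cols.update(dialect)
    df = pd.read_csv(path, sep=sep)
    for key in ("track_id", "time", "x", "y", "z"):
        if cols[key] not in df.columns:
            raise TrackFormatError(f"mandatory column {cols[key]!r} (role {key!r}) missing")
    factor = _unit_factor(position_unit)
    has_speed = cols["speed"] in df.columns
    has_rep = cols["replicate_id"] in df.columns
    has_grp = cols["group_code"] in df.columns

    tracks: list[Track] = []
    for tid, sub in df.groupby(cols["track_id"], sort=False):
        sub = sub.sort_values(cols["time"], kind="stable")
        t = sub[cols["time"]].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise TrackDataError(f"track {tid!r}: non-monotonic or duplicate timestamps")
        xyz = sub[[cols["x"], cols["y"], cols["z"]]].to_numpy(dtype=float) * factor
        speed = sub[cols["speed"]].to_numpy(dtype=float) if has_speed else None
        if speed is not None and np.all(np.isnan(speed)):
            speed = None
        rep = str(sub[cols["replicate_id"]].iloc[0]) if has_rep else ""
        grp = int(sub[cols["group_code"]].iloc[0]) if has_grp else None
        tracks.append(
            Track(str(tid), t, xyz, speed=speed, replicate_id=rep, group_code=grp)
        )
    return tracks


def tracks_to_frame(tracks: Sequence[Track]) -> pd.DataFrame:
    """Flatten tracks into one row per frame with default column names."""
    if not tracks:
        return pd.DataFrame(
            columns=[DEFAULT_DIALECT[k] for k in ("track_id", "time", "x", "y", "z")]
        )
    parts = []
    any_speed = any(tr.speed is not None for tr in tracks)
    any_grp = any(tr.group_code is not None for tr in tracks)
    for tr in tracks:
        d = {
            DEFAULT_DIALECT["track_id"]: tr.track_id,
            DEFAULT_DIALECT["time"]: tr.t,
            DEFAULT_DIALECT["x"]: tr.xyz[:, 0],
            DEFAULT_DIALECT["y"]: tr.xyz[:, 1],
            DEFAULT_DIALECT["z"]: tr.xyz[:, 2],
        }
        if any_speed:
            d[DEFAULT_DIALECT["speed"]] = (
                tr.speed if tr.speed is not None else np.full(tr.n_frames, np.nan)
            )
        d[DEFAULT_DIALECT["replicate_id"]] = tr.replicate_id
        if any_grp:
            d[DEFAULT_DIALECT["group_code"]] = tr.group_code
        parts.append(pd.DataFrame(d))
    return pd.concat(parts, ignore_index=True)


def write_tracks(tracks: Sequence[Track], path, *, sep: str = ",") -> None:
    """Write tracks as a delimited table; inverse of :func:`read_tracks`.

    An empty list yields a header-only file. Floats are written at full
    round-trip precision.
    """
    tracks_to_frame(tracks).to_csv(path, sep=sep, index=False)


def to_world_frame(tracks: Iterable[Track], transform: RigidTransform) -> list[Track]:
    """Apply a camera-to-world rigid motion to every position.

    Times, ids and device speeds are untouched; only xyz changes. The
    marker sits at the world origin after a correct transform.
    """
    return [replace(tr, xyz=transform.apply(tr.xyz)) for tr in tracks]
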
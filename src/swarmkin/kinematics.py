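"""Per-track and per-frame kinematic features.

The downstream classifier uses speed, the three world-frame coordinates
and the derived Euclidean distance from the swarm centre,
d = sqrt(X^2 + Y^2 + Z^2). Device extras (size estimate, acceleration,
raw distance field) are deliberately not features: they are noisy or
redundant with the coordinates.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .errors import TrackDataError
from .filtering import mean_track_speed
from .tracks import Track

__all__ = ["distance_from_origin", "build_feature_table", "FEATURE_COLUMNS"]

#: Stable feature/id column order of the emitted table.
FEATURE_COLUMNS = ["speed_mps", "x_cm", "y_cm", "z_cm", "d_cm", "group_code", "track_id"]


def distance_from_origin(x, y, z):
    """Euclidean distance from the swarm marker (origin), in cm.

    Accepts scalars or arrays; broadcasts element-wise.
    """
    x, y, z = np.asarray(x, float), np.asarray(y, float), np.asarray(z, float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y)) and np.all(np.isfinite(z))):
        raise TrackDataError("non-finite coordinate passed to distance_from_origin")
    return np.sqrt(x * x + y * y + z * z)


def build_feature_table(
    tracks: Sequence[Track],
    *,
    frame_rate: float = 100.0,
    per_track: bool = False,
) -> pd.DataFrame:
    """Build the classifier feature table from (filtered, core) tracks.

    One row per frame by default, matching the study's data-point-level
    modelling; ``per_track=True`` aggregates each track to its means for
    sensitivity analysis. Per-frame speed is the device series when
    present, else the track's chord-length mean speed repeated (the
    per-frame chord speeds are noisier than the track mean and the mean
    is what the filtering stage already certifies).

    Columns: speed_mps, x_cm, y_cm, z_cm, d_cm, group_code, track_id.
    """
    rows = []
    for tr in tracks:
        if tr.speed is not None:
            sp = tr.speed
        else:
            steps = np.linalg.norm(np.diff(tr.xyz, axis=0), axis=1) / 100.0
            dt = np.diff(tr.t)
            inst = steps / dt
            sp = np.concatenate([[inst[0]], inst])  # backward difference, first repeated
        d = distance_from_origin(tr.xyz[:, 0], tr.xyz[:, 1], tr.xyz[:, 2])
        df = pd.DataFrame(
            {
                "speed_mps": sp,
                "x_cm": tr.xyz[:, 0],
                "y_cm": tr.xyz[:, 1],
                "z_cm": tr.xyz[:, 2],
                "d_cm": d,
                "group_code": -1 if tr.group_code is None else tr.group_code,
                "track_id": tr.track_id,
            }
        )
        if per_track:
            df = pd.DataFrame(
                {
                    "speed_mps": [mean_track_speed(tr, frame_rate)],
                    "x_cm": [tr.xyz[:, 0].mean()],
                    "y_cm": [tr.xyz[:, 1].mean()],
                    "z_cm": [tr.xyz[:, 2].mean()],
                    "d_cm": [d.mean()],
                    "group_code": [-1 if tr.group_code is None else tr.group_code],
                    "track_id": [tr.track_id],
                }
            )
        rows.append(df)
    if not rows:
        return pd.DataFrame(columns=FEATURE_COLUMNS)
    return pd.concat(rows, ignore_index=True)[FEATURE_COLUMNS]
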
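"""Recovery coefficients and their permutation statistics.

RC = (image-based total activity in the sphere) / (nominal activity).
The image total is an occupancy-weighted sum on the high-resolution
mask grid (the reconstruction is interpolated up to the mask grid, not
the mask down to the reconstruction grid, which would aggravate voxel
sampling).  Spread across sphere arrangements is summarized by
theta_RC = (RC_max - RC_min) / mean(RC).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .phantom import PhantomConfig, SpherePermutation, neighbor_surface_gaps

RC_COLUMNS = [
    "phantom_type",
    "permutation",
    "arm",
    "updates",
    "diameter_mm",
    "position",
    "rc",
]


def compute_rc(
    activity: np.ndarray,
    occupancy: np.ndarray,
    voxel_volume_ml: float,
    nominal_activity_mbq: float,
) -> float:
    """Occupancy-weighted sphere activity divided by the nominal activity."""
    if nominal_activity_mbq <= 0:
        raise ValueError("nominal activity must be positive")
    if activity.shape != occupancy.shape:
        raise ValueError("activity and occupancy must be on the same grid")
    total = float(np.sum(activity * occupancy)) * voxel_volume_ml
    return total / nominal_activity_mbq


def permutation_stats(records: pd.DataFrame) -> pd.DataFrame:
    """Per-cell RC statistics over sphere arrangements.

    Groups by (phantom_type, arm, updates, diameter_mm) and reports the
    mean/min/max RC, the spread theta_RC = (max - min)/mean, and the
    permutation index and ring position attaining the extremes.
    """
    if records.empty:
        raise ValueError("no RC records")
    rows = []
    keys = ["phantom_type", "arm", "updates", "diameter_mm"]
    for key, g in records.groupby(keys, sort=True):
        rc = g["rc"].to_numpy()
        imin, imax = int(np.argmin(rc)), int(np.argmax(rc))
        mean = float(rc.mean())
        rows.append(
            dict(
                zip(keys, key),
                mean_rc=mean,
                min_rc=float(rc[imin]),
                max_rc=float(rc[imax]),
                theta_rc=(float(rc[imax]) - float(rc[imin])) / mean,
                argmin_permutation=int(g["permutation"].iloc[imin]),
                argmin_position=int(g["position"].iloc[imin]),
                argmax_permutation=int(g["permutation"].iloc[imax]),
                argmax_position=int(g["position"].iloc[imax]),
                n=len(g),
            )
        )
    return pd.DataFrame(rows)


def position_mean_rc(records: pd.DataFrame) -> pd.DataFrame:
    """Mean RC per ring position within each (phantom, arm, updates, d).

    A structured sweep places every diameter at every position, so the
    per-position mean isolates the position effect from the neighbor
    composition and from counting noise; it is the robust small-sample
    analogue of asking which position produced the extreme RC.
    """
    return records.pivot_table(
        index=["phantom_type", "arm", "updates", "diameter_mm"],
        columns="position",
        values="rc",
        aggfunc="mean",
    )


def extreme_configurations(
    stats: pd.DataFrame,
    records: pd.DataFrame,
    config: PhantomConfig,
) -> list[dict]:
    """Extreme-RC arrangements with neighbor metadata, per (arm, diameter).

    For the argmax/argmin permutation of every stats cell the full
    assignment is rebuilt from the record table and the diameters of the
    two ring neighbors plus their surface gaps are attached.
    """
    out = []
    for _, row in stats.iterrows():
        entry = {
            k: row[k] for k in ("phantom_type", "arm", "updates", "diameter_mm")
        }
        for kind in ("argmin", "argmax"):
            perm_idx = int(row[f"{kind}_permutation"])
            pos = int(row[f"{kind}_position"])
            sel = records[
                (records["permutation"] == perm_idx)
                & (records["phantom_type"] == row["phantom_type"])
            ]
            assignment = tuple(
                float(sel[sel["position"] == p]["diameter_mm"].iloc[0])
                for p in range(1, 7)
            )
            perm = SpherePermutation(perm_idx, assignment)
            gaps = neighbor_surface_gaps(config, perm)
            left = pos - 2 if pos > 1 else 5
            right = pos % 6
            entry[kind] = dict(
                permutation=perm_idx,
                position=pos,
                assignment=assignment,
                neighbor_diameters=(assignment[left], assignment[right]),
                neighbor_gaps=(
                    gaps[(left + 1, (left + 1) % 6 + 1)],
                    gaps[(pos, pos % 6 + 1)],
                ),
            )
        out.append(entry)
    return out
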
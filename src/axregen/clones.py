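"""Clone trajectories, binned velocities and scaling analysis.

A clone is the set of descendants of one founder cell; its position is the
mean AP position of its members.  Because the pushing mechanism never lets a
cell pass another, clones preserve their relative AP order, and founders near
the amputation plane end up at the posterior tip of the regenerate.  The
normalized position (relative to the span between the recruitment limit and
the outgrowth tip) is approximately conserved in time — the scaling signature
of regeneration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulator import SimulationResult

__all__ = [
    "CloneTrack",
    "default_founder_targets",
    "track_clones",
    "clone_velocities",
    "normalized_positions",
]


@dataclass(frozen=True)
class CloneTrack:
    """Mean position of one clone over time: columns time_h, mean_position_um, n_cells."""

    clone_id: int
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.samples["time_h"].to_numpy(float)
        if not np.all(np.diff(t) > 0):
            raise ValueError("sample times must be strictly increasing")


def default_founder_targets(
    anterior_limit: float = -1100.0, spacing: float = 50.0
) -> np.ndarray:
    """Founder positions sampled every ``spacing`` um from 0 to the limit."""
    return np.arange(0.0, anterior_limit - 1e-9, -spacing)


def track_clones(
    result: SimulationResult,
    founder_positions=None,
    clone_ids=None,
) -> list[CloneTrack]:
    """Extract clone mean-position tracks from a simulation's snapshots.

    By default founders are the cells initially nearest to every ~50 um from
    the amputation plane back to -1100 um.  Clone ids are the founders'
    initial indices.
    """
    if not result.snapshots:
        raise ValueError("result has no snapshots; set config.snapshot_times")
    if clone_ids is None:
        targets = (
            np.asarray(founder_positions, float)
            if founder_positions is not None
            else default_founder_targets()
        )
        init = result.founder_positions
        clone_ids = sorted({int(np.argmin(np.abs(init - t))) for t in targets})
    known = set()
    for snap in result.snapshots.values():
        known.update(snap["clone_id"].unique().tolist())
    unknown = [c for c in clone_ids if c not in known]
    if unknown:
        raise ValueError(f"unknown clone ids: {unknown}")

    times = sorted(result.snapshots)
    tracks = []
    for cid in clone_ids:
        rows = []
        for t in times:
            snap = result.snapshots[t]
            pos = snap.loc[snap["clone_id"] == cid, "position_um"]
            if len(pos):
                rows.append((t, float(pos.mean()), int(len(pos))))
        tracks.append(
            CloneTrack(
                clone_id=int(cid),
                samples=pd.DataFrame(
                    rows, columns=["time_h", "mean_position_um", "n_cells"]
                ),
            )
        )
    return tracks


def clone_velocities(
    tracks: list[CloneTrack], bin_width: float = 800.0
) -> pd.DataFrame:
    """Mean +/- sd clone velocity (um/day) per AP position bin.

    Each track's samples are grouped by the bin their instantaneous position
    falls in (a track can visit several bins); groups with fewer than two
    samples are dropped; the per-(track, bin) velocity is the ordinary
    least-squares slope of position against time in days.
    """
    if not tracks:
        raise ValueError("need at least one track")
    slopes: dict[float, list[float]] = {}
    for track in tracks:
        t_days = track.samples["time_h"].to_numpy(float) / 24.0
        pos = track.samples["mean_position_um"].to_numpy(float)
        bins = np.floor(pos / bin_width) * bin_width
        for b in np.unique(bins):
            sel = bins == b
            if sel.sum() < 2:
                continue
            slope = np.polyfit(t_days[sel], pos[sel], 1)[0]
            slopes.setdefault(float(b), []).append(float(slope))
    if not slopes:
        warnings.warn("all (track, bin) groups had < 2 samples", RuntimeWarning)
        return pd.DataFrame(
            columns=[
                "bin_start_um",
                "bin_end_um",
                "mean_velocity_um_per_day",
                "sd_velocity",
                "n_tracks",
            ]
        )
    rows = [
        {
            "bin_start_um": b,
            "bin_end_um": b + bin_width,
            "mean_velocity_um_per_day": float(np.mean(v)),
            "sd_velocity": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
            "n_tracks": len(v),
        }
        for b, v in sorted(slopes.items())
    ]
    return pd.DataFrame(rows)


def normalized_positions(
    track: CloneTrack, result: SimulationResult
) -> pd.DataFrame:
    """Clone position normalized to the (xi, outgrowth tip) span, in [0, 1].

    norm(t) = (position(t) - xi(t)) / (outgrowth(t) - xi(t)).  Samples with a
    zero denominator or an undefined xi are skipped with a warning.
    """
    rows = []
    skipped = 0
    for t, pos in zip(
        track.samples["time_h"], track.samples["mean_position_um"]
    ):
        xi = result.value_at("xi", float(t))
        out = result.value_at("outgrowth", float(t))
        denom = out - xi
        if np.isnan(xi) or denom == 0:
            skipped += 1
            continue
        rows.append((float(t), (pos - xi) / denom))
    if skipped:
        warnings.warn(
            f"skipped {skipped} samples with undefined normalization",
            RuntimeWarning,
        )
    return pd.DataFrame(rows, columns=["time_h", "normalized_position"])
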
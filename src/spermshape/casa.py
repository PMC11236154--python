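"""CASA-style track kinematics: VSL, VCL, VAP and motile fractions.

Definitions follow standard computer-assisted sperm analysis conventions:

* **VSL** (straight-line velocity): net displacement from first to last
  point divided by elapsed time.
* **VCL** (curvilinear velocity): total point-to-point path length divided
  by elapsed time.
* **VAP** (average-path velocity): path length of the smoothed ("average")
  trajectory divided by elapsed time. The average path is a centered
  moving average (default window 5 frames) whose window shrinks
  symmetrically at the track ends, so the smoothed path shares its
  endpoints with the raw track.

These choices guarantee ``VCL >= VAP >= VSL`` for every track: smoothing
only contracts path length, and any path between two points is at least as
long as the straight segment joining them. Commercial instruments use
proprietary smoothing and motility criteria; the definitions here are
documented substitutes, with the motility call (default VCL >= 25 µm/s)
exposed as a parameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._exceptions import ParameterError

__all__ = ["Track", "KinematicSummary", "summarize_track", "motile_fraction", "read_tracks", "write_tracks"]


@dataclass(frozen=True)
class Track:
    """Time-stamped 2D positions of one sperm cell (seconds, µm)."""

    track_id: str
    t: np.ndarray
    xy: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        xy = np.asarray(self.xy, dtype=float)
        if t.ndim != 1 or xy.shape != (t.size, 2):
            raise ParameterError(
                f"t must be (n,) and xy (n, 2); got {t.shape} and {xy.shape}"
            )
        if t.size < 2:
            raise ParameterError("a track needs at least 2 frames")
        if np.any(np.diff(t) <= 0):
            raise ParameterError("frame times must be strictly increasing")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "xy", xy)


@dataclass(frozen=True)
class KinematicSummary:
    """Per-track velocity parameters (µm/s) and the motility call."""

    track_id: str
    VSL: float
    VCL: float
    VAP: float
    motile: bool


def _smooth_path(xy: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with symmetric shrink at the ends.

    Point i is averaged over [i - h_i, i + h_i] with
    h_i = min(window // 2, i, n - 1 - i); endpoints are preserved.
    """
    n = xy.shape[0]
    h = window // 2
    out = np.empty_like(xy)
    for i in range(n):
        hi = min(h, i, n - 1 - i)
        out[i] = xy[i - hi : i + hi + 1].mean(axis=0)
    return out


def _path_length(xy: np.ndarray) -> float:
    return float(np.sum(np.linalg.norm(np.diff(xy, axis=0), axis=1)))


def summarize_track(
    track: Track,
    smoothing_window: int = 5,
    motility_threshold: float = 25.0,
) -> KinematicSummary:
    """Compute VSL, VCL, VAP (µm/s) and the motility flag for one track."""
    if smoothing_window < 1 or smoothing_window % 2 == 0:
        raise ParameterError(
            f"smoothing_window must be a positive odd integer, got {smoothing_window}"
        )
    elapsed = float(track.t[-1] - track.t[0])
    vsl = float(np.linalg.norm(track.xy[-1] - track.xy[0])) / elapsed
    vcl = _path_length(track.xy) / elapsed
    vap = _path_length(_smooth_path(track.xy, smoothing_window)) / elapsed
    return KinematicSummary(
        track_id=track.track_id,
        VSL=vsl,
        VCL=vcl,
        VAP=vap,
        motile=bool(vcl >= motility_threshold),
    )


def motile_fraction(summaries) -> float:
    """Share of tracks called motile in a group."""
    summaries = list(summaries)
    if not summaries:
        raise ParameterError("cannot compute a motile fraction of an empty group")
    return float(np.mean([s.motile for s in summaries]))


_TRACK_COLUMNS = ["track_id", "frame", "t_seconds", "x_um", "y_um"]


def write_tracks(path, tracks) -> None:
    """Write tracks as CSV (``track_id,frame,t_seconds,x_um,y_um``)."""
    frames = [
        pd.DataFrame(
            {
                "track_id": tr.track_id,
                "frame": np.arange(tr.t.size),
                "t_seconds": tr.t,
                "x_um": tr.xy[:, 0],
                "y_um": tr.xy[:, 1],
            }
        )
        for tr in tracks
    ]
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=_TRACK_COLUMNS)
    df.to_csv(path, index=False, float_format="%.17g")


def read_tracks(path) -> list[Track]:
    """Read a track CSV back into :class:`Track` records."""
    from ._exceptions import FormatError

    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return []
    missing = [c for c in _TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"track CSV is missing column(s): {', '.join(missing)}")
    return [
        Track(track_id=str(tid), t=grp["t_seconds"].to_numpy(), xy=grp[["x_um", "y_um"]].to_numpy())
        for tid, grp in df.groupby("track_id", sort=False)
    ]
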
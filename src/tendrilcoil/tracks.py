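"""Measurement pipeline on marker trajectories.

Emulates an image-based 3D motion-tracking workflow downstream of marker
coordinate extraction: per-marker bending-angle series, segmentation of the
rapid-coiling ("transform") stage from the stop stage, the coiling-angle
time course at the contact marker, and the stop-stage coil diameter from a
3D circle fit.

A :class:`MarkerTrack` holds the time-indexed 3D coordinates of markers
painted along the tendril at a nominal 5 mm arc-length spacing, one frame
per camera interval (minutes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateGeometryError, ValidationError
from .geometry import bending_angle, fit_circle_3d

__all__ = [
    "MarkerTrack",
    "StageSegmentation",
    "bending_series",
    "coiling_angle_series",
    "plateau_angle",
    "segment_stages",
    "stop_stage_diameter",
    "coil_marker_subset",
    "analyze_track",
]

#: A marker counts as part of the coil when its bending angle is within
#: COIL_BEND_MARGIN deg of the most-bent marker (and below
#: COIL_BEND_THRESHOLD): markers adjacent to the straight/coil junction
#: bend visibly without lying on the coil circle and must stay out of the
#: circle fit.
COIL_BEND_THRESHOLD = 175.0
COIL_BEND_MARGIN = 6.0

TRACK_COLUMNS = ["frame", "time_min", "marker_id", "x_mm", "y_mm", "z_mm"]


@dataclass
class MarkerTrack:
    """Time-indexed 3D marker coordinates.

    Attributes
    ----------
    frame_times : ndarray, shape (T,)
        Strictly increasing times in minutes.
    markers : ndarray, shape (T, M, 3)
        Marker positions in mm; root-most marker first.
    marker_spacing : float
        Nominal arc-length spacing between markers in mm.
    meta : str
        Free-text provenance.
    """

    frame_times: np.ndarray
    markers: np.ndarray
    marker_spacing: float = 5.0
    meta: str = ""

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.markers = np.asarray(self.markers, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.markers.ndim != 3 or self.markers.shape[2] != 3:
            raise ValidationError(
                f"markers must be (T, M, 3), got shape {self.markers.shape}"
            )
        t, m, _ = self.markers.shape
        if m < 3:
            raise ValidationError(f"need at least 3 markers, got {m}")
        if self.frame_times.shape != (t,):
            raise ValidationError(
                f"frame_times length {self.frame_times.shape} does not match "
                f"{t} frames"
            )
        if t >= 2 and not np.all(np.diff(self.frame_times) > 0):
            raise ValidationError("frame_times must be strictly increasing")
        if not np.all(np.isfinite(self.markers)):
            raise ValidationError("markers contain non-finite coordinates")
        if not self.marker_spacing > 0:
            raise ValidationError("marker_spacing must be positive")

    @property
    def n_frames(self) -> int:
        return self.markers.shape[0]

    @property
    def n_markers(self) -> int:
        return self.markers.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        t, m, _ = self.markers.shape
        frames = np.repeat(np.arange(t), m)
        return pd.DataFrame(
            {
                "frame": frames,
                "time_min": np.repeat(self.frame_times, m),
                "marker_id": np.tile(np.arange(m), t),
                "x_mm": self.markers[:, :, 0].ravel(),
                "y_mm": self.markers[:, :, 1].ravel(),
                "z_mm": self.markers[:, :, 2].ravel(),
            }
        )

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.9g")

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, marker_spacing: float = 5.0, meta: str = ""
    ) -> "MarkerTrack":
        missing = [c for c in TRACK_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"track table is missing columns {missing}")
        frames = np.sort(df["frame"].unique())
        n_markers = df["marker_id"].nunique()
        markers = np.empty((len(frames), n_markers, 3))
        times = np.empty(len(frames))
        for k, fr in enumerate(frames):
            sub = df[df["frame"] == fr].sort_values("marker_id")
            ids = sub["marker_id"].to_numpy()
            if len(sub) != n_markers or not np.array_equal(
                ids, np.arange(n_markers)
            ):
                raise ValidationError(
                    f"frame {fr}: expected marker_id 0..{n_markers - 1}, "
                    f"got {ids.tolist()}"
                )
            markers[k] = sub[["x_mm", "y_mm", "z_mm"]].to_numpy()
            times[k] = sub["time_min"].iloc[0]
        return cls(
            frame_times=times,
            markers=markers,
            marker_spacing=marker_spacing,
            meta=meta,
        )

    @classmethod
    def read_csv(
        cls, path, marker_spacing: float = 5.0, meta: str = ""
    ) -> "MarkerTrack":
        df = pd.read_csv(path)
        return cls.from_dataframe(df, marker_spacing=marker_spacing, meta=meta)


@dataclass(frozen=True)
class StageSegmentation:
    """Frame windows of the rapid-coiling (transform) and stop stages.

    Windows are inclusive ``(start_frame, end_frame)`` pairs; a missing
    window is ``None``. The transform window always precedes the stop
    window.
    """

    transform_window: Optional[tuple]
    stop_window: Optional[tuple]

    def __post_init__(self) -> None:
        t, s = self.transform_window, self.stop_window
        for name, w in (("transform_window", t), ("stop_window", s)):
            if w is not None and w[0] > w[1]:
                raise ValidationError(f"{name} {w} has start > end")
        if t is not None and s is not None and t[1] >= s[0]:
            raise ValidationError(
                f"transform window {t} must precede stop window {s}"
            )


def bending_series(track: MarkerTrack) -> np.ndarray:
    """Bending angle (deg) of every interior marker in every frame.

    Returns a ``(T, M-2)`` matrix; column ``i`` is interior marker
    ``i + 1``. Degenerate marker triples yield NaN with a warning rather
    than aborting.
    """
    t, m, _ = track.markers.shape
    out = np.empty((t, m - 2))
    p = track.markers
    a = p[:, :-2, :] - p[:, 1:-1, :]
    c = p[:, 2:, :] - p[:, 1:-1, :]
    na = np.linalg.norm(a, axis=2)
    nc = np.linalg.norm(c, axis=2)
    bad = (na <= 1e-9) | (nc <= 1e-9)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.clip(np.sum(a * c, axis=2) / (na * nc), -1.0, 1.0)
        out = np.degrees(np.arccos(cosang))
    if np.any(bad):
        out[bad] = np.nan
        warnings.warn(
            f"{int(bad.sum())} degenerate marker triple(s) set to NaN",
            stacklevel=2,
        )
    return out


def coiling_angle_series(track: MarkerTrack, contact_index: int) -> np.ndarray:
    """Per-frame coiling angle (deg) at ``contact_index``: 180 - bending."""
    if not 1 <= contact_index <= track.n_markers - 2:
        raise ValueError(
            f"contact_index {contact_index} must be interior "
            f"(1..{track.n_markers - 2})"
        )
    series = bending_series(track)[:, contact_index - 1]
    return 180.0 - series


def segment_stages(
    series, stop_eps: float = 1.0, persistence: int = 3
) -> StageSegmentation:
    """Split an angle series into rapid-coiling and stop stages.

    The stop stage starts at the first frame from which the per-frame angle
    change stays below ``stop_eps`` (deg/frame) for at least ``persistence``
    consecutive frame intervals, searched after the first motion. The
    transform window spans from the first motion to the frame before the
    stop start; the stop window extends to the final frame.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"series must be 1-D, got shape {x.shape}")
    n = len(x)
    if n < persistence + 2:
        raise ValueError(
            f"need at least persistence + 2 = {persistence + 2} frames, got {n}"
        )
    d = np.abs(np.diff(x))
    moving = d >= stop_eps
    if not np.any(moving):
        return StageSegmentation(transform_window=None, stop_window=(0, n - 1))
    first_motion = int(np.argmax(moving))
    quiet = ~moving
    # first run of >= persistence quiet intervals starting after first motion
    stop_start = None
    run = 0
    for j in range(first_motion + 1, len(d)):
        run = run + 1 if quiet[j] else 0
        if run >= persistence:
            stop_start = j - persistence + 2  # frame after last moving interval
            break
    if stop_start is None:
        return StageSegmentation(
            transform_window=(first_motion, n - 1), stop_window=None
        )
    return StageSegmentation(
        transform_window=(first_motion, stop_start - 1),
        stop_window=(stop_start, n - 1),
    )


def plateau_angle(
    series, stop_eps: float = 1.0, persistence: int = 3
) -> float:
    """Mean coiling angle over the detected stop window (the plateau)."""
    seg = segment_stages(series, stop_eps=stop_eps, persistence=persistence)
    if seg.stop_window is None:
        raise ValidationError("no stop stage detected: series never plateaus")
    lo, hi = seg.stop_window
    return float(np.mean(np.asarray(series, dtype=float)[lo : hi + 1]))


def coil_marker_subset(
    track: MarkerTrack,
    frame: int,
    threshold: float = COIL_BEND_THRESHOLD,
    margin: float = COIL_BEND_MARGIN,
) -> np.ndarray:
    """Indices of markers that are part of the coil at ``frame``.

    A marker belongs to the coil when its bending angle is below
    ``threshold`` degrees *and* within ``margin`` degrees of the most-bent
    marker. The margin keeps junction-adjacent markers - which bend
    visibly without lying on the coil circle - out of the circle fit.
    """
    bend = np.nan_to_num(bending_series(track)[frame], nan=180.0)
    interior = np.arange(1, track.n_markers - 1)
    cutoff = min(threshold, float(bend.min()) + margin)
    return interior[bend <= cutoff]


def stop_stage_diameter(
    track: MarkerTrack,
    seg: StageSegmentation,
    marker_subset: Optional[Sequence[int]] = None,
) -> float:
    """Coil diameter (mm) from a 3D circle fit at the stop-window midpoint.

    ``marker_subset`` selects the markers entering the fit; by default the
    coiled markers are auto-selected at the midpoint frame.
    """
    if seg.stop_window is None:
        raise ValidationError("segmentation has no stop window")
    lo, hi = seg.stop_window
    mid = (lo + hi) // 2
    if marker_subset is None:
        marker_subset = coil_marker_subset(track, mid)
    idx = np.asarray(marker_subset, dtype=int)
    if len(idx) < 3:
        raise DegenerateGeometryError(
            f"need >= 3 markers for a circle fit, subset has {len(idx)}"
        )
    return fit_circle_3d(track.markers[mid, idx, :]).diameter


def analyze_track(
    track: MarkerTrack,
    contact_index: Optional[int] = None,
    stop_eps: float = 1.0,
    persistence: int = 3,
) -> dict:
    """Full pipeline on one track: series, stages, plateau, coil diameter.

    Returns a JSON-serialisable report. ``contact_index`` defaults to the
    interior marker with the largest final coiling angle (the most-bent
    marker, normally at the contact).
    """
    series_all = bending_series(track)
    if contact_index is None:
        final_bend = np.nan_to_num(series_all[-1], nan=180.0)
        contact_index = int(np.argmin(final_bend)) + 1
    coil_series = coiling_angle_series(track, contact_index)
    seg = segment_stages(coil_series, stop_eps=stop_eps, persistence=persistence)
    report: dict = {
        "n_frames": track.n_frames,
        "n_markers": track.n_markers,
        "contact_index": int(contact_index),
        "transform_window": list(seg.transform_window)
        if seg.transform_window
        else None,
        "stop_window": list(seg.stop_window) if seg.stop_window else None,
        "coiling_angle_series": [float(v) for v in coil_series],
    }
    if seg.stop_window is not None:
        lo, hi = seg.stop_window
        report["plateau_angle_deg"] = float(np.mean(coil_series[lo : hi + 1]))
        mid = (lo + hi) // 2
        subset = coil_marker_subset(track, mid)
        report["coil_marker_subset"] = [int(i) for i in subset]
        if len(subset) >= 3:
            try:
                report["stop_stage_diameter_mm"] = stop_stage_diameter(
                    track, seg, subset
                )
            except DegenerateGeometryError:
                report["stop_stage_diameter_mm"] = None
        else:
            report["stop_stage_diameter_mm"] = None
    else:
        report["plateau_angle_deg"] = None
        report["stop_stage_diameter_mm"] = None
    return report
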
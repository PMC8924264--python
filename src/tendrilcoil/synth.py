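"""Synthetic fixtures: marker trajectories and coiling-success tables.

Two track generators emulate the motion-capture experiments the analysis
pipeline was built for:

* :func:`gen_free_coil_track` — a tendril briefly touched and released,
  photographed from above at 1-min intervals (12 frames): the coiling angle
  at the contact marker ramps up and plateaus at the minimum coiling angle.
* :func:`gen_wrap_track` — a tendril whose tip region winds onto a circle
  of fixed diameter through a rapid (exponential-approach) stage followed
  by a stop stage; shipped presets ``fig5_thin`` (89 mm tendril, 1 mm rod,
  20.4 mm stop-stage coil) and ``fig6_thick`` (69 mm tendril, 40 mm rod,
  16.1 mm stop-stage coil).

A logistic generator emulates the 87-trial coiling-success experiment over
supports of 10-35 mm diameter.

Every generator is a deterministic function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ValidationError
from .tracks import MarkerTrack

__all__ = [
    "TrackPreset",
    "SuccessGenConfig",
    "SUPPORT_DIAMETER_GRID",
    "TRACK_PRESETS",
    "get_preset",
    "gen_free_coil_track",
    "gen_wrap_track",
    "gen_success_dataset",
]

#: Support diameters (mm) offered in the 87-trial coiling-success experiment.
SUPPORT_DIAMETER_GRID = (10.0, 12.0, 15.0, 18.0, 20.0, 24.0, 30.0, 32.0, 35.0)


@dataclass(frozen=True)
class TrackPreset:
    """Settings for one synthetic marker-track experiment."""

    name: str
    tendril_length: float  # mm
    support_diameter: Optional[float] = None  # mm; None for free coiling
    stop_diameter: Optional[float] = None  # mm coil diameter in the stop stage
    theta_min: float = 25.0  # deg; plateau of the coiling angle
    n_frames: int = 12
    frame_interval: float = 1.0  # minutes
    marker_spacing: float = 5.0  # mm
    noise_sd: float = 0.0  # mm isotropic Gaussian marker jitter
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("tendril_length", "theta_min", "frame_interval",
                     "marker_spacing"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive")
        for name in ("support_diameter", "stop_diameter"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValidationError(f"{name} must be positive when given")
        if self.n_frames < 2:
            raise ValidationError("n_frames must be at least 2")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")
        if self.tendril_length < 3 * self.marker_spacing:
            raise ValidationError(
                "tendril_length too short for 3 markers at this spacing"
            )


TRACK_PRESETS = {
    # 89 mm tendril on a 1 mm rod; stop-stage coil diameter 20.4 mm.
    "fig5_thin": TrackPreset(
        name="fig5_thin",
        tendril_length=89.0,
        support_diameter=1.0,
        stop_diameter=20.4,
        n_frames=30,
    ),
    # 69 mm tendril on a 40 mm rod; stop-stage coil diameter 16.1 mm.
    "fig6_thick": TrackPreset(
        name="fig6_thick",
        tendril_length=69.0,
        support_diameter=40.0,
        stop_diameter=16.1,
        n_frames=30,
    ),
    # touched-and-released tendril, 12 overhead photos at 1-min intervals.
    "fig4_free": TrackPreset(
        name="fig4_free",
        tendril_length=100.0,
        n_frames=12,
    ),
}


def get_preset(name: str, **overrides) -> TrackPreset:
    """Look up a shipped preset by name, optionally overriding fields."""
    try:
        preset = TRACK_PRESETS[name]
    except KeyError:
        raise ValidationError(
            f"unknown preset {name!r}; available: {sorted(TRACK_PRESETS)}"
        ) from None
    return replace(preset, **overrides) if overrides else preset


def _marker_count(preset: TrackPreset) -> int:
    return int(np.floor(preset.tendril_length / preset.marker_spacing)) + 1


def _add_noise(
    markers: np.ndarray, noise_sd: float, seed: int
) -> np.ndarray:
    if noise_sd == 0:
        return markers
    rng = np.random.default_rng(seed)
    return markers + rng.normal(0.0, noise_sd, size=markers.shape)


def gen_free_coil_track(preset: TrackPreset) -> MarkerTrack:
    """Track of a touched-then-released tendril coiling to its plateau.

    Two straight arms hinge at the middle marker; the hinge (coiling) angle
    rises linearly to ``theta_min`` over the first half of the frames, then
    holds, so the plateau of the recovered coiling-angle series equals
    ``theta_min`` exactly in the noiseless case.
    """
    m = _marker_count(preset)
    contact = m // 2
    rise_frames = max(1, preset.n_frames // 2 - 1)
    spacing = preset.marker_spacing
    times = np.arange(preset.n_frames) * preset.frame_interval
    markers = np.zeros((preset.n_frames, m, 3))
    for k in range(preset.n_frames):
        c = np.radians(preset.theta_min * min(1.0, k / rise_frames))
        # proximal arm along +x
        markers[k, : contact + 1, 0] = np.arange(contact + 1) * spacing
        # distal arm rotated by the coiling angle
        direction = np.array([np.cos(-c), np.sin(-c), 0.0])
        steps = np.arange(1, m - contact)[:, None] * spacing
        markers[k, contact + 1 :] = markers[k, contact] + steps * direction
    markers = _add_noise(markers, preset.noise_sd, preset.seed)
    return MarkerTrack(
        frame_times=times,
        markers=markers,
        marker_spacing=spacing,
        meta=f"synthetic free-coil track preset={preset.name}",
    )


def gen_wrap_track(preset: TrackPreset) -> MarkerTrack:
    """Track of a tendril tip winding onto a circle of ``stop_diameter``.

    The coiled arc length approaches its final value exponentially, with
    the rate set so that 80% of the final wrap is reached by one-third of
    the frames (rapid coiling stage), after which the shape barely changes
    (stop stage). Markers on the coiled part lie exactly on the stop-stage
    circle, so in the noiseless case a circle fit recovers
    ``stop_diameter`` to machine precision.
    """
    if preset.stop_diameter is None:
        raise ValidationError("wrap tracks require stop_diameter")
    spacing = preset.marker_spacing
    if preset.stop_diameter < 2 * spacing / np.pi:
        raise ValidationError(
            f"stop_diameter {preset.stop_diameter} mm is unresolvable by "
            f"markers spaced {spacing} mm apart"
        )
    m = _marker_count(preset)
    length = (m - 1) * spacing  # arc length actually covered by markers
    rho = preset.stop_diameter / 2.0
    a_final = min(length - 2 * spacing, np.pi * preset.stop_diameter)
    if a_final < 3 * spacing:
        raise ValidationError(
            "tendril too short to wind 3 markers onto the stop circle"
        )
    rate = 3.0 * np.log(5.0) / preset.n_frames
    times = np.arange(preset.n_frames) * preset.frame_interval
    arcs = np.arange(m) * spacing
    markers = np.empty((preset.n_frames, m, 3))
    for k in range(preset.n_frames):
        a_k = a_final * (1.0 - np.exp(-rate * k))
        s_j = length - a_k  # arc position of the straight/coil junction
        straight = arcs <= s_j
        markers[k, straight, 0] = arcs[straight]
        markers[k, straight, 1] = 0.0
        u = arcs[~straight] - s_j  # arc length into the coil
        phi = u / rho
        markers[k, ~straight, 0] = s_j + rho * np.sin(phi)
        markers[k, ~straight, 1] = rho * (1.0 - np.cos(phi))
        markers[k, :, 2] = 0.0
    markers = _add_noise(markers, preset.noise_sd, preset.seed)
    return MarkerTrack(
        frame_times=times,
        markers=markers,
        marker_spacing=spacing,
        meta=f"synthetic wrap track preset={preset.name}",
    )


@dataclass(frozen=True)
class SuccessGenConfig:
    """Generative stand-in for the 87-trial coiling-success experiment.

    Success is Bernoulli with
    ``logit(p) = beta0 + beta_diameter * D + beta_length * L`` (per-mm
    coefficients on the logit scale). Defaults mirror the experimental
    pattern: success falls with support diameter and rises with tendril
    length.
    """

    n_trials: int = 87
    diameter_grid: Tuple[float, ...] = SUPPORT_DIAMETER_GRID
    length_range: Tuple[float, float] = (40.0, 160.0)
    beta0: float = 1.0
    beta_diameter: float = -0.25
    beta_length: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValidationError("n_trials must be >= 1")
        if len(self.diameter_grid) == 0:
            raise ValidationError("diameter_grid must be non-empty")
        if any(d <= 0 for d in self.diameter_grid):
            raise ValidationError("diameters must be positive")
        lo, hi = self.length_range
        if not 0 < lo <= hi:
            raise ValidationError("length_range must be positive and ordered")


def gen_success_dataset(cfg: SuccessGenConfig) -> pd.DataFrame:
    """Draw a (diameter_mm, length_mm, success) table from the logistic model."""
    rng = np.random.default_rng(cfg.seed)
    diameters = rng.choice(np.asarray(cfg.diameter_grid, float), cfg.n_trials)
    lengths = rng.uniform(*cfg.length_range, cfg.n_trials)
    logits = cfg.beta0 + cfg.beta_diameter * diameters + cfg.beta_length * lengths
    p = 1.0 / (1.0 + np.exp(-logits))
    success = (rng.random(cfg.n_trials) < p).astype(int)
    return pd.DataFrame(
        {"diameter_mm": diameters, "length_mm": lengths, "success": success}
    )
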
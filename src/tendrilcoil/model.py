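"""Two-rule kinematic simulator of tendril coiling around a cylindrical support.

The model implements two behavioural rules inferred from observation:

1. **Coil from the contact point** — once a tendril touches a support it
   deposits intrinsic curvature into its joints starting at the contact
   point and progressing tip-ward, at a fixed angular rate, up to the
   curvature of its free coil (``2 / free_coil_diameter``).
2. **Minimum coiling angle** — once coiling has started the contact region
   always bends by at least ``theta_min``. A support of diameter ``phi``
   can only keep the initial contact point if its surface curvature
   ``2/phi`` supplies that bend over the short stimulated arc
   (``contact_window``); otherwise the contact lifts off and is re-detected
   tip-ward, producing the "moving contact point" response. The critical
   diameter is ``phi_crit = 2 * contact_window / radians(theta_min)``
   (about 11.5 mm at the defaults).

Geometry is planar and quasi-static: the tendril is an inextensible chain
of ``ds``-long segments pinned at the root, with per-joint intrinsic bend.
Each time step the chain's placement angle at the root is solved so that
the chain rests tangent to the support circle without penetrating it.
Slow circumnutation of the plant is modelled as a seeded AR(1) drift of
the root pin; it is the only stochastic element (zero ``jitter_sd`` gives
a fully deterministic trial) and is what occasionally presses the
root-side free segment onto the support, triggering the secondary contact
that starts clip-shape coiling.

Each trial is classified into the three-step decision tree
(continuous coiling / moving contact point -> tip contact / clip shape
coiling -> success / detach).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import ValidationError

__all__ = [
    "ModelParams",
    "Support",
    "TendrilState",
    "PhaseRecord",
    "Trajectory",
    "CoilSimulation",
    "detect_contact",
    "simulate",
    "simulate_free",
    "classify_phases",
    "phase_diagram",
]

STEP1_WINDOW_MIN = 5.0  # initial-response observation window (minutes)
PENETRATION_TOL = 1e-6  # mm


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the two-rule coiling model.

    Lengths in mm, angles in degrees, times in minutes.
    """

    theta_min: float = 25.0  # minimum coiling angle (deg)
    free_coil_diameter: float = 18.0  # intrinsic free-coil diameter (mm)
    coiling_rate: float = 20.0  # curvature uptake (deg/min)
    contact_window: float = 2.5  # stimulated arc for the theta_min demand (mm)
    contact_tol: float = 0.25  # touch distance (mm)
    stop_eps: float = 0.5  # quiescence threshold (deg/frame)
    root_contact_fraction: float = 0.5  # arc fraction counting as "at the root"
    detach_wrap_threshold: float = 360.0  # wrap angle for coiling success (deg)
    detach_persistence: float = 10.0  # minutes without contact before detach
    max_time: float = 180.0  # observation window (min)
    jitter_sd: float = 2.0  # circumnutation drift innovation (mm / step)
    jitter_rho: float = 0.98  # AR(1) memory of the drift
    dt: float = 0.5  # time step (min)
    ds: float = 2.5  # segment length (mm)
    seed: int = 0

    def __post_init__(self) -> None:
        positive = (
            "theta_min", "free_coil_diameter", "coiling_rate",
            "contact_window", "contact_tol", "stop_eps",
            "detach_wrap_threshold", "detach_persistence", "max_time",
            "dt", "ds",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive")
        if self.theta_min > 180:
            raise ValidationError("theta_min must be <= 180 deg")
        if not 0 < self.root_contact_fraction <= 1:
            raise ValidationError("root_contact_fraction must be in (0, 1]")
        if self.jitter_sd < 0:
            raise ValidationError("jitter_sd must be non-negative")
        if not 0 <= self.jitter_rho < 1:
            raise ValidationError("jitter_rho must be in [0, 1)")

    @property
    def phi_crit(self) -> float:
        """Largest support diameter (mm) that holds the initial contact."""
        return 2.0 * self.contact_window / np.radians(self.theta_min)

    @property
    def joint_cap(self) -> float:
        """Per-joint intrinsic bend cap (deg) at free-coil curvature."""
        return np.degrees(2.0 * self.ds / self.free_coil_diameter)


@dataclass(frozen=True)
class Support:
    """Circular cross-section of the support rod."""

    center: np.ndarray  # (3,) mm; z ignored in the planar simulation
    diameter: float  # mm

    def __post_init__(self) -> None:
        if not self.diameter > 0:
            raise ValidationError("support diameter must be positive")
        object.__setattr__(
            self, "center", np.asarray(self.center, dtype=float)
        )

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


@dataclass
class TendrilState:
    """Discretised tendril: node positions plus per-joint intrinsic bend."""

    nodes: np.ndarray  # (n, 3) mm
    ds: float
    joint_bend: np.ndarray  # (n,) deg; entries 1..n-2 meaningful
    active_contact: Optional[int] = None

    @property
    def length(self) -> float:
        return (len(self.nodes) - 1) * self.ds


@dataclass(frozen=True)
class PhaseRecord:
    """Three-step decision-tree outcome of one trial."""

    step1: str  # continuous_coiling | moving_contact_point
    step2: str  # not_applicable | tip_contact | clip_shape_coiling
    step3: str  # success | detach
    time_to_detach: Optional[float]  # minutes
    total_wrap: float  # deg

    def __post_init__(self) -> None:
        if (self.step1 == "continuous_coiling") != (
            self.step2 == "not_applicable"
        ):
            raise ValidationError(
                "step2 must be not_applicable exactly for continuous coiling"
            )
        if (self.step3 == "detach") != (self.time_to_detach is not None):
            raise ValidationError(
                "time_to_detach must be present exactly for detach outcomes"
            )
        if self.time_to_detach is not None and self.time_to_detach < 0:
            raise ValidationError("time_to_detach must be non-negative")

    def to_dict(self) -> dict:
        return {
            "step1": self.step1,
            "step2": self.step2,
            "step3": self.step3,
            "time_to_detach": self.time_to_detach,
            "total_wrap": self.total_wrap,
        }


@dataclass
class Trajectory:
    """Recorded simulation: frames, contact history and events."""

    times: List[float]
    frames: List[np.ndarray]  # (n, 3) node positions per recorded frame
    contact_history: List[Tuple[float, Optional[int]]]
    wrap_history: List[Tuple[float, float]]
    events: List[Tuple[float, str]]
    params: ModelParams
    support: Optional[Support]
    length: float

    def event_time(self, label: str) -> Optional[float]:
        for t, lab in self.events:
            if lab == label:
                return t
        return None

    def has_event(self, label: str) -> bool:
        return self.event_time(label) is not None

    def frames_dataframe(self) -> pd.DataFrame:
        rows = []
        contact = dict(
            zip([t for t, _ in self.contact_history],
                [c for _, c in self.contact_history])
        )
        for t, nodes in zip(self.times, self.frames):
            c = contact.get(t)
            for i, (x, y, z) in enumerate(nodes):
                rows.append((t, i, x, y, z, int(c == i) if c is not None else 0))
        return pd.DataFrame(
            rows,
            columns=["time_min", "node_id", "x_mm", "y_mm", "z_mm",
                     "contact_flag"],
        )

    def events_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.events, columns=["time_min", "event"])


def detect_contact(
    state: TendrilState, support: Support, contact_tol: float
) -> Optional[int]:
    """Root-most node within ``contact_tol`` of the support surface.

    Nodes penetrating the support are projected onto its surface before
    the distance test, so they count as touching.
    """
    xy = state.nodes[:, :2]
    center = support.center[:2]
    dist = np.linalg.norm(xy - center, axis=1)
    clearance = np.maximum(dist - support.radius, 0.0)
    touching = np.nonzero(clearance <= contact_tol)[0]
    return int(touching[0]) if len(touching) else None


def _winding(xy: np.ndarray, center: np.ndarray) -> float:
    """Signed angle (deg) subtended by the polyline around ``center``."""
    ang = np.unwrap(np.arctan2(xy[:, 1] - center[1], xy[:, 0] - center[0]))
    return float(np.degrees(ang[-1] - ang[0]))


class CoilSimulation:
    """One quasi-static coiling trial.

    Create with a tendril length (mm) and either a support diameter or
    ``support_diameter=None`` for free coiling (a touched-and-released
    tendril curling to its intrinsic coil). Call :meth:`run` for the full
    trajectory or :meth:`step` to advance one time step.
    """

    def __init__(
        self,
        length: float,
        support_diameter: Optional[float],
        params: Optional[ModelParams] = None,
        contact_position: float = 0.5,
        record_frames: bool = True,
        support_gap: float = 0.0,
    ) -> None:
        p = params or ModelParams()
        if not length > 2 * p.ds:
            raise ValidationError(
                f"tendril length must exceed 2*ds = {2 * p.ds} mm, got {length}"
            )
        if support_diameter is not None and not support_diameter > 0:
            raise ValidationError(
                f"support diameter must be positive, got {support_diameter}"
            )
        if not 0 < contact_position < 1:
            raise ValidationError("contact_position must be in (0, 1)")
        self.params = p
        self.n = int(round(length / p.ds)) + 1
        self.length = (self.n - 1) * p.ds
        self.k0 = int(round(contact_position * (self.n - 1)))
        self.k0 = min(max(self.k0, 1), self.n - 2)
        self.record_frames = record_frames
        self.rng = np.random.default_rng(p.seed)

        self.base_pin = np.zeros(2)
        self.drift = np.zeros(2)
        contact_x = self.k0 * p.ds
        if support_diameter is None:
            self.support = None
        else:
            r = support_diameter / 2.0
            self.support = Support(
                center=np.array([contact_x, -(r + support_gap), 0.0]),
                diameter=support_diameter,
            )

        # intrinsic per-joint bend (deg); entries 1..n-2 used
        self.b = np.zeros(self.n)
        self.fill_front = self.k0  # next joint to receive primary bend
        self.deposited = 0.0  # total deposited bend since contact (deg)
        self.psi = 0.0  # placement angle at the root pin (rad)
        self.time = 0.0
        self.k_contact: Optional[int] = None
        self.k_min = 0  # root-most node eligible as the primary contact
        self.lifted = False
        self.liftoff_emitted = False
        self.tip_emitted = False
        self.contact_started = False
        self.no_contact_time = 0.0
        self.terminal: Optional[str] = None

        # clip-shape coiling state
        self.clip_node: Optional[int] = None
        self.clip_front: Optional[int] = None
        self.clip_frozen: Optional[np.ndarray] = None  # (n - s, 2) nodes s..n-1
        self.clip_heading: Optional[float] = None
        self.clip_sense = 1.0

        if self.support is not None:
            self.maintained = self.support.diameter <= p.phi_crit
        else:
            self.maintained = True

        self.traj = Trajectory(
            times=[], frames=[], contact_history=[], wrap_history=[],
            events=[], params=p, support=self.support, length=self.length,
        )
        self._initialize()

    # ----- geometry -------------------------------------------------

    def _realize(self, psi: float) -> np.ndarray:
        """Node xy positions for placement angle ``psi`` at the root pin."""
        turns = -np.radians(self.b[1 : self.n - 1])
        heads = psi + np.concatenate(([0.0], np.cumsum(turns)))
        steps = self.params.ds * np.column_stack(
            [np.cos(heads), np.sin(heads)]
        )
        pin = self.base_pin + self.drift
        return np.vstack([pin, pin + np.cumsum(steps, axis=0)])

    def _clearance(self, xy: np.ndarray) -> np.ndarray:
        c = self.support.center[:2]
        return np.linalg.norm(xy - c, axis=1) - self.support.radius

    def _solve_placement(self) -> Tuple[np.ndarray, np.ndarray]:
        """Rotate the chain about the root pin until it rests tangent.

        Finds psi with min clearance over the eligible nodes equal to zero
        and no node penetrating; falls back to whole-curve tangency when
        the lifted-off curl would otherwise be pressed into the support.
        """
        lo_idx = self.k_min

        def g(psi: float, idx: int) -> float:
            return float(np.min(self._clearance(self._realize(psi))[idx:]))

        def solve(idx: int) -> Optional[float]:
            p0 = self.psi
            g0 = g(p0, idx)
            if abs(g0) < 1e-12:
                return p0
            # clearance increases with psi (rotating the chain away from
            # the support, which lies below the root-pin axis)
            step = 0.01 if g0 < 0 else -0.01
            p1 = p0
            for _ in range(60):
                p1 = p1 + step
                g1 = g(p1, idx)
                if g0 * g1 <= 0:
                    lo, hi = (p0, p1) if p0 < p1 else (p1, p0)
                    return brentq(lambda q: g(q, idx), lo, hi, xtol=1e-12)
                step *= 1.4
                if abs(p1 - p0) > np.pi:
                    return None
            return None

        psi = solve(lo_idx)
        if psi is not None:
            xy = self._realize(psi)
            cl = self._clearance(xy)
            if np.min(cl) >= -PENETRATION_TOL:
                self.psi = psi
                return xy, cl
        # eligible tangency impossible without pressing an ineligible node
        # into the support: rest the whole curve on it instead
        psi = solve(0)
        if psi is None:
            # cannot reach the support at all from this placement
            xy = self._realize(self.psi)
            return xy, self._clearance(xy)
        self.psi = psi
        xy = self._realize(psi)
        return xy, self._clearance(xy)

    # ----- clip-shape reconstruction --------------------------------

    def _realize_clip(self) -> np.ndarray:
        """Rebuild nodes 0..s-1 by wrapping the root arm around the support.

        Joints take their intrinsic bend, greedily clamped at surface
        tangency so the arm hugs the support instead of penetrating it.
        """
        s = self.clip_node
        frozen = self.clip_frozen
        xy = np.empty((self.n, 2))
        xy[s:] = frozen
        h = self.clip_heading  # heading from node s toward node s-1
        sense = self.clip_sense
        c = self.support.center[:2]
        r = self.support.radius
        pos = xy[s].copy()
        heading = h
        for j in range(s - 1, -1, -1):
            if j < s - 1:
                heading += sense * np.radians(self.b[j + 1])
            desired = heading

            def clear_at(hd: float) -> float:
                cand = pos + self.params.ds * np.array(
                    [np.cos(hd), np.sin(hd)]
                )
                return float(np.linalg.norm(cand - c) - r)

            if clear_at(desired) < 0:
                # back the turn off toward tangency
                away = desired
                for _ in range(12):
                    away -= sense * 0.12
                    if clear_at(away) >= 0:
                        break
                if clear_at(away) >= 0:
                    lo, hi = sorted((away, desired))
                    desired = brentq(clear_at, lo, hi, xtol=1e-12)
                else:
                    desired = away
            heading = desired
            pos = pos + self.params.ds * np.array(
                [np.cos(heading), np.sin(heading)]
            )
            xy[j] = pos
        return xy[::1]

    # ----- bookkeeping ----------------------------------------------

    def _emit(self, label: str) -> None:
        self.traj.events.append((self.time, label))

    def _record(self, xy: np.ndarray, wrap: float) -> None:
        self.traj.contact_history.append((self.time, self.k_contact))
        self.traj.wrap_history.append((self.time, wrap))
        if self.record_frames:
            nodes3 = np.column_stack([xy, np.zeros(len(xy))])
            self.traj.times.append(self.time)
            self.traj.frames.append(nodes3)

    def _initialize(self) -> None:
        if self.support is None:
            xy = self._realize(self.psi)
            self.contact_started = True  # virtual touch-and-release stimulus
            self.wrap0 = 0.0
            self._record(xy, 0.0)
            return
        xy, cl = self._place()
        m = self._find_contact(cl)
        if m is not None:
            self.k_contact = m
            self.contact_started = True
            self._emit("initial_contact")
        self.wrap0 = abs(_winding(xy, self.support.center[:2]))
        self._record(xy, 0.0)

    def _place(self) -> Tuple[np.ndarray, np.ndarray]:
        """Natural placement before contact; tangency-resolved afterwards.

        A tendril that has never touched the support keeps its natural
        placement unless that placement penetrates (first touch); once
        contact is established the chain rests tangent on the support.
        """
        if self.contact_started:
            return self._solve_placement()
        xy = self._realize(self.psi)
        cl = self._clearance(xy)
        if np.min(cl) < -PENETRATION_TOL:
            return self._solve_placement()
        return xy, cl

    def _find_contact(self, cl: np.ndarray) -> Optional[int]:
        idx = np.nonzero(cl <= self.params.contact_tol)[0]
        return int(idx[0]) if len(idx) else None

    # ----- dynamics -------------------------------------------------

    def _deposit_primary(self, budget: float) -> float:
        cap = self.params.joint_cap
        used = 0.0
        while budget > 1e-12 and self.fill_front <= self.n - 2:
            room = cap - self.b[self.fill_front]
            take = min(room, budget)
            self.b[self.fill_front] += take
            budget -= take
            used += take
            if self.b[self.fill_front] >= cap - 1e-12:
                self.fill_front += 1
        return used

    def _deposit_free(self, budget: float) -> None:
        """Free coiling: saturate joints tip-ward from the stimulus, then
        root-ward, so the whole tendril converges to the free coil."""
        used = self._deposit_primary(budget)
        budget -= used
        cap = self.params.joint_cap
        j = self.k0 - 1
        while budget > 1e-12 and j >= 1:
            room = cap - self.b[j]
            take = min(room, budget)
            self.b[j] += take
            budget -= take
            if self.b[j] >= cap - 1e-12:
                j -= 1
        self.deposited += 0.0

    def _deposit_clip(self, budget: float) -> None:
        cap = self.params.joint_cap
        while budget > 1e-12 and self.clip_front >= 1:
            room = cap - self.b[self.clip_front]
            take = min(room, budget)
            self.b[self.clip_front] += take
            budget -= take
            if self.b[self.clip_front] >= cap - 1e-12:
                self.clip_front -= 1

    def step(self, dt: Optional[float] = None) -> List[str]:
        """Advance one time step; returns the labels of new events."""
        if dt is None:
            dt = self.params.dt
        if dt <= 0:
            raise ValidationError(f"dt must be positive, got {dt}")
        if self.terminal is not None:
            return []
        p = self.params
        n_events_before = len(self.traj.events)
        self.time += dt

        # circumnutation drift of the root pin
        if p.jitter_sd > 0 and self.clip_node is None:
            self.drift = p.jitter_rho * self.drift + self.rng.normal(
                0.0, p.jitter_sd, 2
            )

        budget = p.coiling_rate * dt
        if self.contact_started:
            if self.support is None:
                self._deposit_free(budget)
            elif self.clip_node is not None:
                self._deposit_clip(budget)
            elif self.k_contact is not None:
                used = self._deposit_primary(budget)
                self.deposited += used

        # minimum-coiling-angle rule: a support too flat to supply
        # theta_min over the stimulated arc loses the initial contact
        if (
            self.support is not None
            and self.contact_started
            and not self.maintained
            and not self.lifted
            and self.deposited >= p.theta_min
        ):
            self.lifted = True
            if not self.liftoff_emitted:
                self._emit("liftoff")
                self.liftoff_emitted = True

        if self.support is None:
            xy = self._realize(self.psi)
            wrap = 0.0
            self._record(xy, wrap)
            if self.fill_front > self.n - 2 and np.all(
                self.b[1 : self.n - 1] >= p.joint_cap - 1e-9
            ):
                self.terminal = "free_coil_complete"
            if self.time >= p.max_time:
                self.terminal = self.terminal or "timeout"
            return [lab for _, lab in self.traj.events[n_events_before:]]

        if self.clip_node is not None:
            xy = self._realize_clip()
        else:
            if self.lifted:
                self.k_min = min(self.fill_front + 1, self.n - 1)
            xy, cl = self._place()
            m = self._find_contact(cl)
            self._update_contact(m, cl)

        wrap = max(
            0.0, abs(_winding(xy, self.support.center[:2])) - self.wrap0
        )
        self._record(xy, wrap)
        self._check_terminal(wrap)
        return [lab for _, lab in self.traj.events[n_events_before:]]

    def _update_contact(self, raw: Optional[int], cl: np.ndarray) -> None:
        p = self.params
        if raw is None:
            self.no_contact_time += p.dt
            if (
                self.contact_started
                and not self.maintained
                and self.no_contact_time >= p.detach_persistence
                and self.terminal is None
            ):
                self._emit("detach")
                self.terminal = "detach"
            return
        self.no_contact_time = 0.0
        if not self.contact_started:
            self.k_contact = raw
            self.contact_started = True
            self._emit("initial_contact")
            self.wrap0 = abs(
                _winding(self._realize(self.psi), self.support.center[:2])
            )
            return
        if self.lifted:
            # the migrating contact: root-most touching node ahead of the
            # curled region; monotone by the moving-contact mechanism
            elig = np.nonzero(
                cl[self.k_min :] <= p.contact_tol
            )[0]
            if len(elig):
                m = int(elig[0]) + self.k_min
                if self.k_contact is None or m > self.k_contact:
                    if self.k_contact is not None:
                        self._emit("new_contact")
                    self.k_contact = m
            if (
                self.k_contact is not None
                and self.k_contact >= self.n - 1
                and not self.tip_emitted
            ):
                self._emit("tip_reached")
                self.tip_emitted = True
        else:
            self.k_contact = raw

        # secondary contact of the root-side free segment
        if self.lifted and self.clip_node is None:
            root_limit = p.root_contact_fraction * self.length
            arm_end = min(self.k0, self.fill_front)
            arm = np.arange(0, arm_end)
            if len(arm):
                touching = arm[cl[arm] <= p.contact_tol]
                touching = touching[touching * p.ds <= root_limit]
                if len(touching):
                    self._start_clip(int(touching[np.argmin(cl[touching])]))

    def _start_clip(self, s: int) -> None:
        if s < 2:
            return
        self._emit("secondary_contact_root")
        xy = self._realize(self.psi)
        self.clip_node = s
        self.clip_front = s - 1
        self.clip_frozen = xy[s:].copy()
        vec = xy[s - 1] - xy[s]
        self.clip_heading = float(np.arctan2(vec[1], vec[0]))
        c = self.support.center[:2]
        to_center = c - xy[s]
        cross = vec[0] * to_center[1] - vec[1] * to_center[0]
        self.clip_sense = 1.0 if cross >= 0 else -1.0

    def _check_terminal(self, wrap: float) -> None:
        if self.terminal is not None:
            return
        p = self.params
        # wrap-closure counts as a grip only while the contact is held
        # (continuous coiling) or after a clip has formed; a lifted tendril
        # rolling over the support may transiently enclose it without
        # gripping
        gripping = not self.lifted or self.clip_node is not None
        if gripping and wrap >= p.detach_wrap_threshold:
            self._emit("wrap_closed")
            self.terminal = "wrap_closed"
            return
        if self.clip_node is not None:
            if self.clip_front < 1:
                self._emit("detach")
                self.terminal = "detach"
            return
        if (
            self.lifted
            and self.fill_front > self.n - 2
            and self.clip_node is None
        ):
            if not self.tip_emitted:
                self._emit("tip_reached")
                self.tip_emitted = True
            self._emit("detach")
            self.terminal = "detach"
            return
        if self.time >= p.max_time:
            self.terminal = "timeout"
            return
        # quiescent continuous coil: the coil encircles the support and the
        # curvature budget is exhausted, so nothing can change any more
        if self.maintained and self.fill_front > self.n - 2:
            self.terminal = "quiescent"

    def run(self) -> Trajectory:
        guard = int(np.ceil(self.params.max_time / self.params.dt)) + 2
        for _ in range(guard):
            if self.terminal is not None or self.time >= self.params.max_time:
                break
            self.step()
        return self.traj

    @property
    def state(self) -> TendrilState:
        if self.clip_node is not None:
            xy = self._realize_clip()
        else:
            xy = self._realize(self.psi)
        return TendrilState(
            nodes=np.column_stack([xy, np.zeros(self.n)]),
            ds=self.params.ds,
            joint_bend=self.b.copy(),
            active_contact=self.k_contact
            if self.clip_node is None
            else self.clip_node,
        )


def simulate(
    length: float,
    support_diameter: float,
    params: Optional[ModelParams] = None,
    contact_position: float = 0.5,
    record_frames: bool = True,
) -> Trajectory:
    """Run one trial: straight tendril, support tangent at the contact point.

    Deterministic given ``params.seed``.
    """
    sim = CoilSimulation(
        length=length,
        support_diameter=support_diameter,
        params=params,
        contact_position=contact_position,
        record_frames=record_frames,
    )
    return sim.run()


def simulate_free(
    length: float,
    params: Optional[ModelParams] = None,
    contact_position: float = 0.5,
) -> Trajectory:
    """Free coiling of a touched-and-released tendril (no obstacle)."""
    sim = CoilSimulation(
        length=length,
        support_diameter=None,
        params=params,
        contact_position=contact_position,
    )
    return sim.run()


def classify_phases(
    traj: Trajectory, params: Optional[ModelParams] = None
) -> PhaseRecord:
    """Classify a trajectory into the three-step decision tree."""
    p = params or traj.params
    t0 = traj.event_time("initial_contact")
    if t0 is None:
        raise ValidationError("no coiling started: trajectory has no contact")
    # the initial response: did the minimum-coiling-angle rule force the
    # contact off its initial point within the observation window?
    t_lift = traj.event_time("liftoff")
    moved = t_lift is not None and t_lift <= t0 + STEP1_WINDOW_MIN
    step1 = "moving_contact_point" if moved else "continuous_coiling"
    if step1 == "continuous_coiling":
        step2 = "not_applicable"
    elif traj.has_event("secondary_contact_root"):
        step2 = "clip_shape_coiling"
    else:
        step2 = "tip_contact"
    total_wrap = max((w for _, w in traj.wrap_history), default=0.0)
    t_detach = traj.event_time("detach")
    if t_detach is not None:
        step3 = "detach"
        ttd: Optional[float] = t_detach - t0
    else:
        step3 = "success"
        ttd = None
    return PhaseRecord(
        step1=step1,
        step2=step2,
        step3=step3,
        time_to_detach=ttd,
        total_wrap=total_wrap,
    )


def phase_diagram(
    lengths: Sequence[float],
    diameters: Sequence[float],
    params: Optional[ModelParams] = None,
    seeds: Sequence[int] = (0,),
) -> pd.DataFrame:
    """Full-factorial sweep over tendril length x support diameter x seed.

    Per-cell simulation errors are recorded in the ``error`` column
    instead of aborting the sweep.
    """
    if len(lengths) == 0 or len(diameters) == 0 or len(seeds) == 0:
        raise ValidationError("lengths, diameters and seeds must be non-empty")
    p = params or ModelParams()
    rows = []
    for length in lengths:
        for diameter in diameters:
            for seed in seeds:
                cell = {
                    "length_mm": length,
                    "diameter_mm": diameter,
                    "seed": seed,
                }
                try:
                    traj = simulate(
                        length,
                        diameter,
                        params=replace(p, seed=int(seed)),
                        record_frames=False,
                    )
                    rec = classify_phases(traj)
                    cell.update(rec.to_dict())
                    cell["error"] = None
                except Exception as exc:  # recorded, not raised
                    cell.update(
                        step1=None, step2=None, step3=None,
                        time_to_detach=None, total_wrap=None,
                        error=str(exc),
                    )
                rows.append(cell)
    return pd.DataFrame(rows)
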
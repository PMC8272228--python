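"""Synthetic thermal-session generator.

Emulates what a thermal camera sees during an isolated resistance-training
session of the upper arm: a warm elliptical arm on a cool background, a
localized hotspot over the target muscle whose amplitude follows
piecewise-linear skin-temperature dynamics (slow rise during exercise, faster
rise during recovery, plateau/decay after a few minutes of recovery), a
diffuse arm-wide warming component, and additive Gaussian sensor noise at the
camera's thermal sensitivity.

The hotspot amplitude is calibrated so that the *mean* temperature increment
over the target-muscle region (upper half for deltoid, lower-left quadrant
for biceps, lower-right quadrant for triceps — the same regions the heat-map
analysis uses) equals the modeled cumulative offset.  Downstream region-mean
trajectories therefore reproduce the configured elevation rates, which is the
property the simulator is for.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, InvalidProtocolError
from .protocol import MuscleClass, SessionProtocol, frame_times
from .thermal_io import ThermalFrame


@dataclass(frozen=True)
class ArmGeometry:
    """Rotated ellipse standing in for the arm silhouette.

    ``center`` and ``axes`` are in pixels, ``(row, col)`` order; ``axes`` are
    the semi-axes.  ``rotation_deg`` rotates the ellipse counterclockwise.
    """

    center: tuple[float, float]
    axes: tuple[float, float]
    rotation_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.axes[0] <= 0 or self.axes[1] <= 0:
            raise ConfigError("ellipse semi-axes must be positive")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated session.

    Defaults follow the camera and the measured dynamics: 640 x 512 sensor,
    noise at the 0.05 °C thermal sensitivity, skin-temperature elevation of
    0.13 °C/min during exercise and 0.47 °C/min during recovery with a
    plateau after 3 min of recovery.  Baseline skin (33 °C) and ambient
    (25 °C) temperatures are plausible defaults for an exposed arm indoors.
    """

    frame_shape: tuple[int, int] = (512, 640)
    frame_interval_s: float = 4.0
    baseline_skin_C: float = 33.0
    ambient_C: float = 25.0
    exercise_rate: float = 0.13   # °C/min while moving the weight
    recovery_rate: float = 0.47   # °C/min during recovery, before the plateau
    plateau_after_min: float = 3.0
    post_plateau_rate: float = -0.05  # °C/min after the plateau (<= 0)
    nontarget_fraction: float = 0.3   # diffuse arm-wide share of the warming
    hotspot_sigma: float = 46.0       # px, spatial spread of the hotspot (~0.09 x rows)
    noise_sd: float = 0.05            # °C, camera NETD
    arm_geometry: ArmGeometry | None = None
    diffuse_only: bool = False        # "vague" scene: warming with no hotspot
    hotspot_center: tuple[float, float] | None = None  # overrides muscle_center
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ambient_C >= self.baseline_skin_C:
            raise ConfigError("ambient_C must be below baseline_skin_C")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if not 0.0 <= self.nontarget_fraction <= 1.0:
            raise ConfigError("nontarget_fraction must be in [0, 1]")
        if self.hotspot_sigma <= 0:
            raise ConfigError("hotspot_sigma must be positive")
        if self.post_plateau_rate > 0:
            raise ConfigError("post_plateau_rate must be <= 0")
        if self.arm_geometry is None:
            rows, cols = self.frame_shape
            geom = ArmGeometry(
                center=(rows / 2.0, cols / 2.0),
                axes=(rows * 0.40, cols * 0.28),
            )
            object.__setattr__(self, "arm_geometry", geom)


@dataclass
class SessionRecording:
    """Ordered thermal frames plus the protocol that produced them."""

    frames: list[ThermalFrame]
    protocol: SessionProtocol
    subject_id: str = ""
    session_id: str = ""

    def __post_init__(self) -> None:
        ts = [f.timestamp_s for f in self.frames]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise InvalidProtocolError("frame timestamps must be strictly increasing")
        shapes = {f.shape for f in self.frames}
        if len(shapes) > 1:
            raise InvalidProtocolError(f"frames have inconsistent shapes: {shapes}")

    @property
    def timestamps(self) -> np.ndarray:
        return np.array([f.timestamp_s for f in self.frames])


def muscle_center(region: MuscleClass, geometry: ArmGeometry) -> tuple[float, float]:
    """Hotspot center for a target muscle, inside the arm ellipse.

    Deltoid sits in the upper half of the arm region, biceps in the
    lower-left quadrant and triceps in the lower-right quadrant (image
    aligned so the biceps side faces left).
    """
    region = MuscleClass(region)
    if region is MuscleClass.VAGUE:
        raise ConfigError("the vague class has no muscle center")
    a_r, a_c = geometry.axes
    # centers sit at 0.45 of the semi-axes: inside the muscle's grid region
    # but clear of the silhouette edge, where a hotspot would be unphysical
    offsets = {
        MuscleClass.DELTOID: (-0.45 * a_r, 0.0),
        MuscleClass.BICEPS: (0.45 * a_r, -0.45 * a_c),
        MuscleClass.TRICEPS: (0.45 * a_r, 0.45 * a_c),
    }
    dr, dc = offsets[region]
    theta = math.radians(geometry.rotation_deg)
    rr = dr * math.cos(theta) - dc * math.sin(theta)
    cc = dr * math.sin(theta) + dc * math.cos(theta)
    return (geometry.center[0] + rr, geometry.center[1] + cc)


def _phase_segments(protocol: SessionProtocol, config: SimulationConfig):
    """(t_start, t_end_or_inf, rate °C/min) segments of the temperature model.

    Active sets rise at ``exercise_rate``; each recovery rises at
    ``recovery_rate`` for ``plateau_after_min`` minutes, then follows
    ``post_plateau_rate``.  The final recovery extends indefinitely.
    A zero-weight (passive/control) protocol has zero rates throughout.
    """
    passive = protocol.weight_kg == 0
    ex = 0.0 if passive else config.exercise_rate
    rec = 0.0 if passive else config.recovery_rate
    post = 0.0 if passive else config.post_plateau_rate
    plateau_s = config.plateau_after_min * 60.0

    times = frame_times(protocol)
    segs: list[tuple[float, float, float]] = []
    for i in range(protocol.n_sets):
        s_t = times[2 * i][1]
        e_t = times[2 * i + 1][1]
        segs.append((s_t, e_t, ex))
        rec_end = e_t + protocol.recovery_s if i < protocol.n_sets - 1 else math.inf
        knee = e_t + plateau_s
        if knee >= rec_end:
            segs.append((e_t, rec_end, rec))
        else:
            segs.append((e_t, knee, rec))
            segs.append((knee, rec_end, post))
    return segs


def target_offset(t: float, protocol: SessionProtocol, config: SimulationConfig) -> float:
    """Cumulative target-muscle temperature offset at time ``t`` (°C).

    Piecewise-linear integral of the phase rates; continuous in ``t`` with
    ``target_offset(0) == 0``.
    """
    if t < 0:
        raise ConfigError(f"time must be >= 0, got {t}")
    total = 0.0
    for t0, t1, rate in _phase_segments(protocol, config):
        if t <= t0:
            break
        dt = min(t, t1) - t0
        total += rate * dt / 60.0
    return total


class _Scene:
    """Precomputed spatial fields for one (protocol, config) pair."""

    def __init__(self, protocol: SessionProtocol, config: SimulationConfig):
        self.protocol = protocol
        self.config = config
        geom = config.arm_geometry
        rows, cols = config.frame_shape
        rr, cc = np.mgrid[0:rows, 0:cols]
        theta = math.radians(geom.rotation_deg)
        dr = rr - geom.center[0]
        dc = cc - geom.center[1]
        # rotate into the ellipse frame
        u = dr * math.cos(theta) + dc * math.sin(theta)
        v = -dr * math.sin(theta) + dc * math.cos(theta)
        self.arm_mask = (u / geom.axes[0]) ** 2 + (v / geom.axes[1]) ** 2 <= 1.0
        if not self.arm_mask.any():
            raise ConfigError("arm ellipse does not intersect the frame")

        if config.diffuse_only:
            self.gauss = np.zeros((rows, cols))
            self.region_gain = 1.0
            return

        center = config.hotspot_center or muscle_center(protocol.target_muscle, geom)
        d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
        self.gauss = np.exp(-d2 / (2.0 * config.hotspot_sigma**2))

        # Region of the arm bounding box that the heat-map analysis assigns
        # to the target muscle; the hotspot is normalized to its mean there.
        arm_rows, arm_cols = np.nonzero(self.arm_mask)
        r0, r1 = arm_rows.min(), arm_rows.max()
        c0, c1 = arm_cols.min(), arm_cols.max()
        rmid = r0 + (r1 - r0 + 1) / 2.0
        cmid = c0 + (c1 - c0 + 1) / 2.0
        m = MuscleClass(protocol.target_muscle)
        if m is MuscleClass.DELTOID:
            region = rr < rmid
        elif m is MuscleClass.BICEPS:
            region = (rr >= rmid) & (cc < cmid)
        else:
            region = (rr >= rmid) & (cc >= cmid)
        sel = self.arm_mask & region
        self.region_gain = float(self.gauss[sel].mean())

    def render(self, t: float, rng: np.random.Generator | None = None) -> ThermalFrame:
        cfg = self.config
        offset = target_offset(t, self.protocol, cfg)
        img = np.full(cfg.frame_shape, cfg.ambient_C)
        if cfg.diffuse_only:
            warming = offset
        else:
            diffuse = cfg.nontarget_fraction * offset
            amp = (1.0 - cfg.nontarget_fraction) * offset / self.region_gain
            warming = diffuse + amp * self.gauss[self.arm_mask]
        img[self.arm_mask] = cfg.baseline_skin_C + warming
        if cfg.noise_sd > 0 and rng is not None:
            img = img + rng.normal(0.0, cfg.noise_sd, size=img.shape)
        if self.protocol.arm_side == "right":
            img = img[:, ::-1]
        return ThermalFrame(np.ascontiguousarray(img), timestamp_s=float(t))


def render_frame(
    t: float,
    protocol: SessionProtocol,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> ThermalFrame:
    """Render a single thermal frame of the session at time ``t``.

    Pixels outside the arm ellipse sit at ``ambient_C``; arm pixels at
    ``baseline_skin_C`` plus diffuse warming plus the target hotspot, plus
    i.i.d. Gaussian noise of sd ``noise_sd`` when an ``rng`` is given.
    """
    return _Scene(protocol, config).render(t, rng)


def simulate_session(
    protocol: SessionProtocol,
    config: SimulationConfig,
    subject_id: str = "sim",
    session_id: str = "session-0",
    tail_s: float = 0.0,
) -> SessionRecording:
    """Simulate a full session: frames at multiples of ``frame_interval_s``.

    The recording covers the whole protocol timeline (through the end of the
    last set, plus ``tail_s`` seconds of final recovery if requested);
    reproducible bit-for-bit under ``config.seed``.
    """
    if config.frame_interval_s <= 0:
        raise ConfigError("frame_interval_s must be positive")
    last = frame_times(protocol)[-1][1] + tail_s
    n = math.ceil(last / config.frame_interval_s)
    ts = [i * config.frame_interval_s for i in range(n + 1)]
    scene = _Scene(protocol, config)
    rng = np.random.default_rng(config.seed) if config.noise_sd > 0 else None
    frames = [scene.render(t, rng) for t in ts]
    return SessionRecording(frames=frames, protocol=protocol, subject_id=subject_id, session_id=session_id)
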
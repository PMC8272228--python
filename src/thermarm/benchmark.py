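"""Synthetic study generation: batches of labeled simulated sessions.

Composes the simulator with the processing pipeline to produce the inputs
the analyses consume: lists of (heat-map set, activation label) pairs with
per-session variation in baseline temperature, elevation rates and hotspot
placement.  The "vague" class is simulated as diffuse arm-wide warming with
no localized hotspot.

Sessions default to the multi-muscle study protocol (3 sets x 12 reps at 15
reps/min, 92 s recovery) and to small frames so that whole studies run in
seconds; the spatial layout and dynamics are unchanged by the frame size.
"""

from __future__ import annotations

import numpy as np

from .heatmap import HeatMapSet, select_set_heatmaps
from .protocol import MuscleClass, SessionProtocol, TARGET_MUSCLES
from .simulate import ArmGeometry, SessionRecording, SimulationConfig, muscle_center, simulate_session

#: Frame size used for simulated studies (keeps a >= 60x20-px arm ROI).
STUDY_FRAME_SHAPE = (128, 96)


def _study_geometry(frame_shape: tuple[int, int]) -> ArmGeometry:
    rows, cols = frame_shape
    return ArmGeometry(center=(rows / 2.0, cols / 2.0), axes=(rows * 0.40, cols * 0.28))


def study_config(
    target: MuscleClass,
    seed: int,
    rng: np.random.Generator | None = None,
    frame_shape: tuple[int, int] = STUDY_FRAME_SHAPE,
    noise_sd: float = 0.05,
    randomize: bool = False,
) -> SimulationConfig:
    """Simulation conditions for one session.

    With ``randomize`` the baseline temperature, elevation rates, hotspot
    spread and hotspot position (jittered within the muscle's region) vary
    across sessions, emulating between-subject variability; otherwise the
    default study dynamics are used exactly.
    """
    geom = _study_geometry(frame_shape)
    sigma = 0.09 * frame_shape[0]
    kwargs: dict = {}
    if randomize:
        if rng is None:
            rng = np.random.default_rng(seed)
        kwargs["baseline_skin_C"] = rng.uniform(32.5, 33.5)
        kwargs["exercise_rate"] = rng.uniform(0.10, 0.16)
        kwargs["recovery_rate"] = rng.uniform(0.38, 0.56)
        sigma = sigma * rng.uniform(0.85, 1.15)
        if target is not MuscleClass.VAGUE:
            cr, cc = muscle_center(target, geom)
            a_r, a_c = geom.axes
            kwargs["hotspot_center"] = (
                cr + rng.uniform(-0.12, 0.12) * a_r,
                cc + rng.uniform(-0.12, 0.12) * a_c,
            )
    return SimulationConfig(
        frame_shape=frame_shape,
        noise_sd=noise_sd,
        hotspot_sigma=sigma,
        arm_geometry=geom,
        diffuse_only=target is MuscleClass.VAGUE,
        seed=seed,
        **kwargs,
    )


def simulate_study(
    n_per_class: dict[MuscleClass, int],
    seed: int = 0,
    frame_shape: tuple[int, int] = STUDY_FRAME_SHAPE,
    noise_sd: float = 0.05,
    randomize: bool = False,
) -> list[tuple[SessionRecording, MuscleClass]]:
    """Simulate labeled sessions, ``n_per_class[label]`` per activation class.

    A "vague" session still runs a concrete exercise protocol (the labels
    describe what the heat maps show, not what was attempted) but renders
    diffuse warming only.
    """
    rng = np.random.default_rng(seed)
    out: list[tuple[SessionRecording, MuscleClass]] = []
    i = 0
    for label, count in n_per_class.items():
        label = MuscleClass(label)
        for _ in range(count):
            target = label if label is not MuscleClass.VAGUE else TARGET_MUSCLES[i % 3]
            protocol = SessionProtocol(
                target_muscle=target,
                arm_side="left" if rng.integers(2) == 0 else "right",
            )
            config = study_config(
                label,
                seed=int(rng.integers(2**31 - 1)),
                rng=rng,
                frame_shape=frame_shape,
                noise_sd=noise_sd,
                randomize=randomize,
            )
            out.append(
                (
                    simulate_session(protocol, config, session_id=f"sim-{label.value}-{i:03d}"),
                    label,
                )
            )
            i += 1
    return out


def heatmap_sets(
    recordings: list[tuple[SessionRecording, MuscleClass]]
) -> list[tuple[HeatMapSet, MuscleClass]]:
    """Run preprocessing + gridding on every recording."""
    return [(select_set_heatmaps(rec), label) for rec, label in recordings]


def classifier_benchmark_sessions(
    n_per_class: int = 50, seed: int = 0
) -> list[tuple[HeatMapSet, MuscleClass]]:
    """The standard synthetic classification benchmark.

    ``n_per_class`` randomized sessions for each of the four classes
    (including vague), sensor noise at the camera sensitivity (0.05 °C).
    """
    counts = {c: n_per_class for c in (list(TARGET_MUSCLES) + [MuscleClass.VAGUE])}
    recs = simulate_study(counts, seed=seed, randomize=True)
    return heatmap_sets(recs)
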
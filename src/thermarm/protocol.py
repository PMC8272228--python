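"""Training protocols and set/recovery timing arithmetic.

A session consists of ``n_sets`` sets of ``reps_per_set`` repetitions
performed at a fixed cadence (repetitions per minute), optionally including a
passive hold at the end of each set, with a fixed recovery interval between
sets.  All timestamps are seconds from the first frame of the session (t = 0
at the start of the first set); the pre-session acclimation period is outside
the recorded timeline.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .errors import InvalidProtocolError


class MuscleClass(str, enum.Enum):
    """The four activation classes.

    ``biceps``, ``triceps`` and ``deltoid`` are the three target muscles of
    the upper arm; ``vague`` means no valid localized muscle activation was
    observed (used only as a classifier label, never as a training target).
    """

    BICEPS = "biceps"
    TRICEPS = "triceps"
    DELTOID = "deltoid"
    VAGUE = "vague"


#: The three muscles that can be targeted by an exercise.
TARGET_MUSCLES = (MuscleClass.BICEPS, MuscleClass.TRICEPS, MuscleClass.DELTOID)


def set_duration(reps: int, rep_rate: float, passive_s: float = 0.0) -> float:
    """Duration of one set in seconds.

    ``reps`` repetitions at ``rep_rate`` repetitions per minute, plus an
    optional passive (no-movement) hold of ``passive_s`` seconds.

    >>> set_duration(12, 15)
    48.0
    >>> set_duration(8, 15, passive_s=4)
    36.0
    """
    if reps < 1:
        raise InvalidProtocolError(f"reps must be >= 1, got {reps}")
    if rep_rate <= 0:
        raise InvalidProtocolError(f"rep_rate must be positive, got {rep_rate}")
    if passive_s < 0:
        raise InvalidProtocolError(f"passive_s must be >= 0, got {passive_s}")
    return reps / rep_rate * 60.0 + passive_s


@dataclass(frozen=True)
class SessionProtocol:
    """One training session: sets, repetitions, cadence and recovery.

    Parameters
    ----------
    n_sets : int
        Number of sets in the session (>= 1).
    reps_per_set : int
        Repetitions per set (>= 1).
    rep_rate : float
        Cadence in repetitions per minute (> 0); the study cadence is 15.
    passive_s : float
        Passive (no-movement) seconds appended to each set.
    recovery_s : float
        Recovery seconds between consecutive sets.
    weight_kg : float
        Dumbbell weight; 0 encodes passive/control training.
    target_muscle : MuscleClass
        The muscle the exercise isolates (never ``vague``).
    arm_side : str
        ``"left"`` or ``"right"``.
    """

    n_sets: int = 3
    reps_per_set: int = 12
    rep_rate: float = 15.0
    passive_s: float = 0.0
    recovery_s: float = 92.0
    weight_kg: float = 10.0
    target_muscle: MuscleClass = MuscleClass.BICEPS
    arm_side: str = "left"

    def __post_init__(self) -> None:
        if self.n_sets < 1:
            raise InvalidProtocolError(f"n_sets must be >= 1, got {self.n_sets}")
        if self.reps_per_set < 1:
            raise InvalidProtocolError(f"reps_per_set must be >= 1, got {self.reps_per_set}")
        if self.rep_rate <= 0:
            raise InvalidProtocolError(f"rep_rate must be > 0, got {self.rep_rate}")
        if self.passive_s < 0 or self.recovery_s < 0:
            raise InvalidProtocolError("passive_s and recovery_s must be >= 0")
        if self.n_sets > 1 and self.recovery_s == 0:
            # back-to-back sets would collapse E_i and S_{i+1} onto one instant
            raise InvalidProtocolError("multi-set protocols need a positive recovery_s")
        if self.weight_kg < 0:
            raise InvalidProtocolError(f"weight_kg must be >= 0, got {self.weight_kg}")
        muscle = MuscleClass(self.target_muscle)
        if muscle is MuscleClass.VAGUE:
            raise InvalidProtocolError("target_muscle cannot be 'vague'")
        object.__setattr__(self, "target_muscle", muscle)
        if self.arm_side not in ("left", "right"):
            raise InvalidProtocolError(f"arm_side must be 'left' or 'right', got {self.arm_side!r}")

    @property
    def set_duration_s(self) -> float:
        """Duration of one set, including the passive hold."""
        return set_duration(self.reps_per_set, self.rep_rate, self.passive_s)

    def to_dict(self) -> dict:
        return {
            "n_sets": self.n_sets,
            "reps_per_set": self.reps_per_set,
            "rep_rate": self.rep_rate,
            "passive_s": self.passive_s,
            "recovery_s": self.recovery_s,
            "weight_kg": self.weight_kg,
            "target_muscle": self.target_muscle.value,
            "arm_side": self.arm_side,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SessionProtocol":
        return cls(
            n_sets=int(d["n_sets"]),
            reps_per_set=int(d["reps_per_set"]),
            rep_rate=float(d["rep_rate"]),
            passive_s=float(d.get("passive_s", 0.0)),
            recovery_s=float(d["recovery_s"]),
            weight_kg=float(d["weight_kg"]),
            target_muscle=MuscleClass(d["target_muscle"]),
            arm_side=d["arm_side"],
        )


def frame_times(protocol: SessionProtocol) -> list[tuple[str, float]]:
    """Timestamps of the frames chosen for heat maps: start/end of each set.

    Returns ``[(label, seconds), ...]`` with labels S1, E1, ..., Sn, En.
    S1 is at t = 0; each E_i follows its S_i by the set duration; each
    S_{i+1} follows E_i by the recovery interval.  Timestamps are strictly
    increasing and there are exactly ``2 * n_sets`` of them.

    >>> frame_times(SessionProtocol(n_sets=3, reps_per_set=12, recovery_s=92))
    [('S1', 0.0), ('E1', 48.0), ('S2', 140.0), ('E2', 188.0), ('S3', 280.0), ('E3', 328.0)]
    """
    dur = protocol.set_duration_s
    times: list[tuple[str, float]] = []
    t = 0.0
    for i in range(1, protocol.n_sets + 1):
        times.append((f"S{i}", t))
        t += dur
        times.append((f"E{i}", t))
        t += protocol.recovery_s
    return times


def pair_labels(n_sets: int = 3) -> list[tuple[str, str]]:
    """Admissible difference-heat-map pairs, earliest comparison first.

    For the standard 3-set session these are (S1,E1), (S1,S2), (S1,E2),
    (S1,S3), (S1,E3): the start of the first set paired against every later
    selection time.  Ordered so that later pairs win ties when ranking.
    """
    out: list[tuple[str, str]] = []
    for i in range(1, n_sets + 1):
        if i > 1:
            out.append(("S1", f"S{i}"))
        out.append(("S1", f"E{i}"))
    return out
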
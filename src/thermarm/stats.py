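"""Temperature-rate computations, region-difference trajectories, order test.

Elevation rates are average temperature changes per minute over a defined
exercise or recovery phase, reported at the study's 2-decimal precision.
The training-order analysis asks whether the order in which the three
muscles were exercised affects the per-muscle temperature rise; being a
small-sample, non-normal comparison of three independent groups it uses the
Kruskal–Wallis rank test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ThermArmError
from .heatmap import HeatMapSet, region_means
from .protocol import MuscleClass, TARGET_MUSCLES


@dataclass(frozen=True)
class RateResult:
    """An elevation rate over one phase, with its endpoints."""

    rate: float          # raw °C/min
    t_start_s: float
    t_end_s: float
    T_start: float
    T_end: float

    @property
    def rate_reported(self) -> float:
        """Rate rounded half-even to 2 decimals, the study's print precision."""
        return round(self.rate, 2)


@dataclass(frozen=True)
class OrderTestResult:
    """Kruskal–Wallis H, its p-value and the group sizes."""

    H: float
    p: float
    group_sizes: tuple[int, ...]


def elevation_rate(T_start: float, T_end: float, duration_min: float) -> float:
    """Average temperature elevation rate in °C/min, reported at 2 decimals.

    >>> elevation_rate(35.98, 36.11, 1.0)
    0.13
    """
    return rate_result(T_start, T_end, duration_min).rate_reported


def rate_result(
    T_start: float,
    T_end: float,
    duration_min: float,
    t_start_s: float = 0.0,
) -> RateResult:
    """Full rate record (raw value retained) for one phase."""
    if duration_min <= 0:
        raise ThermArmError(f"duration must be positive, got {duration_min} min")
    rate = (T_end - T_start) / duration_min
    return RateResult(
        rate=rate,
        t_start_s=t_start_s,
        t_end_s=t_start_s + duration_min * 60.0,
        T_start=T_start,
        T_end=T_end,
    )


def _ordered_labels(hm_set: HeatMapSet) -> list[str]:
    return sorted(hm_set.labels, key=lambda lab: (int(lab[1:]), lab[0] == "E"))


def region_difference_trajectory(
    hm_set: HeatMapSet, target: MuscleClass
) -> dict[str, list[tuple[str, float]]]:
    """Target-minus-nontarget region means at each selection time of a session.

    Returns ``{nontarget_muscle: [(label, Δ°C), ...]}`` for both nontarget
    muscles, labels ordered S1, E1, ..., Sn, En.
    """
    target = MuscleClass(target)
    if target is MuscleClass.VAGUE:
        raise ThermArmError("trajectories require a concrete target muscle")
    nontargets = [m for m in TARGET_MUSCLES if m is not target]
    out: dict[str, list[tuple[str, float]]] = {m.value: [] for m in nontargets}
    for label in _ordered_labels(hm_set):
        summary = region_means(hm_set[label])
        for m in nontargets:
            out[m.value].append((label, summary[target] - summary[m]))
    return out


def mean_difference_trajectory(
    sessions: list[tuple[HeatMapSet, MuscleClass]]
) -> pd.DataFrame:
    """Across-session mean ± sd of target-vs-nontarget differences.

    One row per (label, nontarget) with columns ``mean`` and ``sd``.
    """
    if not sessions:
        raise ThermArmError("no sessions given")
    rows = []
    for hm_set, target in sessions:
        for nontarget, series in region_difference_trajectory(hm_set, target).items():
            for label, delta in series:
                rows.append({"label": label, "nontarget": nontarget, "delta": delta})
    df = pd.DataFrame(rows)
    agg = df.groupby(["label", "nontarget"])["delta"].agg(["mean", "std"]).reset_index()
    return agg.rename(columns={"std": "sd"})


def phase_rates(hm_set: HeatMapSet, protocol) -> dict[str, list[RateResult]]:
    """Per-phase elevation rates of the target muscle from a session's maps.

    Exercise rates are computed from each set's S→E region means, recovery
    rates from each E→next-S pair, using the protocol's phase durations.
    """
    from .protocol import frame_times  # local import to avoid a cycle

    times = dict(frame_times(protocol))
    target = protocol.target_muscle
    means = {lab: region_means(hm_set[lab])[target] for lab in hm_set.labels}
    out: dict[str, list[RateResult]] = {"exercise": [], "recovery": []}
    for i in range(1, protocol.n_sets + 1):
        s, e = f"S{i}", f"E{i}"
        dur_min = (times[e] - times[s]) / 60.0
        out["exercise"].append(rate_result(means[s], means[e], dur_min, t_start_s=times[s]))
        nxt = f"S{i + 1}"
        if nxt in means:
            rec_min = (times[nxt] - times[e]) / 60.0
            out["recovery"].append(rate_result(means[e], means[nxt], rec_min, t_start_s=times[e]))
    return out


def _h_statistic(values: np.ndarray, sizes: np.ndarray) -> float:
    """Kruskal–Wallis H from a pooled sample, with tie correction."""
    n = values.size
    ranks = sps.rankdata(values)
    h = 0.0
    start = 0
    for sz in sizes:
        r = ranks[start : start + sz].sum()
        h += r * r / sz
        start += sz
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(values, return_counts=True)
    tie = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    if tie == 0:
        return 0.0
    return h / tie


def kruskal_wallis(
    groups: list[np.ndarray | list[float]],
    permutation_reps: int | None = None,
    seed: int = 0,
) -> OrderTestResult:
    """Kruskal–Wallis rank test across two or more independent groups.

    H is the tie-corrected rank-sum statistic; p comes from the chi-squared
    approximation with ``k - 1`` degrees of freedom, or — for tiny groups —
    from a Monte-Carlo permutation null when ``permutation_reps`` is given.
    """
    if len(groups) < 2:
        raise ThermArmError("kruskal_wallis needs at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ThermArmError("all groups must be nonempty")
    sizes = tuple(a.size for a in arrays)
    pooled = np.concatenate(arrays)
    if np.unique(pooled).size == 1:
        # complete ties: no evidence of a location difference
        return OrderTestResult(H=0.0, p=1.0, group_sizes=sizes)
    H, p = sps.kruskal(*arrays)
    if permutation_reps is not None:
        rng = np.random.default_rng(seed)
        szarr = np.array(sizes)
        count = 0
        vals = pooled.copy()
        for _ in range(permutation_reps):
            rng.shuffle(vals)
            if _h_statistic(vals, szarr) >= H - 1e-12:
                count += 1
        p = (count + 1) / (permutation_reps + 1)
    return OrderTestResult(H=float(H), p=float(p), group_sizes=sizes)


def null_rejection_rate(
    n_groups: int = 3,
    group_size: int = 10,
    reps: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Fraction of null (same-distribution) simulations rejected at ``alpha``.

    Calibration check: should sit near ``alpha`` when the chi-squared
    approximation is adequate.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(reps):
        groups = rng.standard_normal((n_groups, group_size))
        _, p = sps.kruskal(*groups)
        if p < alpha:
            rejections += 1
    return rejections / reps
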
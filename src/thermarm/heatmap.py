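"""Grid heat maps, difference heat maps, muscle-region summaries, pair ranking.

The segmented arm ROI is divided into a fixed grid (default 60 rows x 20
columns).  Each cell holds the mean temperature of its foreground pixels;
cells with less than half their pixels on the arm are missing (NaN).  The
grid is split into three anatomical regions: the upper half is the deltoid,
the lower-left quadrant the biceps and the lower-right quadrant the triceps
(images are aligned with the biceps side on the left).  Difference heat maps
subtract an earlier map from a later one cellwise, so heating is positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import RegionUndefinedError, ResolutionError, ThermArmError, TimelineError
from .preprocess import ArmMask, preprocess_frame
from .protocol import MuscleClass, frame_times, pair_labels
from .simulate import SessionRecording
from .thermal_io import ThermalFrame

#: Grid resolution: 20 divisions along the width, 60 along the height.
DEFAULT_GRID = (60, 20)

#: Minimum foreground-pixel fraction for a cell to be non-missing.
MIN_CELL_COVERAGE = 0.5


@dataclass(frozen=True)
class HeatMap:
    """One grid of mean temperatures (°C); NaN marks missing cells."""

    cells: np.ndarray
    label: str = ""
    session_id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.cells, dtype=float)
        if arr.ndim != 2:
            raise ThermArmError(f"heat map must be 2-D, got shape {arr.shape}")
        object.__setattr__(self, "cells", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.cells.shape


@dataclass(frozen=True)
class DifferenceHeatMap:
    """Cellwise later-minus-earlier temperature change (Δ°C)."""

    cells: np.ndarray
    pair: tuple[str, str]
    session_id: str = ""

    @property
    def shape(self) -> tuple[int, int]:
        return self.cells.shape

    @property
    def pair_name(self) -> str:
        return f"{self.pair[0]}-{self.pair[1]}"


@dataclass(frozen=True)
class HeatMapSet:
    """The labeled heat maps of one session (S1..Sn, E1..En)."""

    maps: dict[str, HeatMap]

    def __post_init__(self) -> None:
        if not self.maps:
            raise ThermArmError("heat-map set is empty")
        shapes = {m.shape for m in self.maps.values()}
        if len(shapes) > 1:
            raise ThermArmError(f"inconsistent grid shapes in set: {shapes}")
        sids = {m.session_id for m in self.maps.values()}
        if len(sids) > 1:
            raise ThermArmError(f"mixed session ids in set: {sids}")

    def __getitem__(self, label: str) -> HeatMap:
        return self.maps[label]

    def __len__(self) -> int:
        return len(self.maps)

    @property
    def session_id(self) -> str:
        return next(iter(self.maps.values())).session_id

    @property
    def labels(self) -> list[str]:
        return list(self.maps)


@dataclass(frozen=True)
class RegionSummary:
    """Mean temperature (or change) per muscle region."""

    deltoid: float
    biceps: float
    triceps: float

    def __getitem__(self, muscle: MuscleClass) -> float:
        return {
            MuscleClass.DELTOID: self.deltoid,
            MuscleClass.BICEPS: self.biceps,
            MuscleClass.TRICEPS: self.triceps,
        }[MuscleClass(muscle)]


def _cell_edges(n_pixels: int, n_cells: int) -> np.ndarray:
    """Near-equal cell boundaries; cell sizes differ by at most one pixel."""
    return np.floor(np.arange(n_cells + 1) * n_pixels / n_cells).astype(int)


def make_heatmap(
    roi_frame: ThermalFrame,
    roi_mask: ArmMask,
    n_rows: int = DEFAULT_GRID[0],
    n_cols: int = DEFAULT_GRID[1],
    label: str = "",
    session_id: str = "",
) -> HeatMap:
    """Reduce a segmented ROI to an ``n_rows`` x ``n_cols`` grid of means.

    The ROI bounding box is partitioned into near-equal rectangles (cell
    extents differ by at most one pixel); each cell is the mean of its
    foreground pixels, and a cell whose foreground fraction is below
    :data:`MIN_CELL_COVERAGE` is missing (NaN).
    """
    h, w = roi_frame.shape
    if h < n_rows or w < n_cols:
        raise ResolutionError(
            f"ROI {h}x{w} is smaller than the {n_rows}x{n_cols} grid"
        )
    if roi_frame.shape != roi_mask.shape:
        raise ThermArmError("ROI frame and mask shapes differ")
    temps = roi_frame.temperatures
    m = roi_mask.mask
    redges = _cell_edges(h, n_rows)
    cedges = _cell_edges(w, n_cols)

    masked = np.where(m, temps, 0.0)
    # summed-area tables give each cell's masked sum/count in O(1)
    sum_t = np.zeros((h + 1, w + 1))
    sum_m = np.zeros((h + 1, w + 1))
    sum_t[1:, 1:] = masked.cumsum(0).cumsum(1)
    sum_m[1:, 1:] = m.astype(float).cumsum(0).cumsum(1)

    def block(table, r0, r1, c0, c1):
        return table[r1, c1] - table[r0, c1] - table[r1, c0] + table[r0, c0]

    cells = np.full((n_rows, n_cols), np.nan)
    for i in range(n_rows):
        r0, r1 = redges[i], redges[i + 1]
        for j in range(n_cols):
            c0, c1 = cedges[j], cedges[j + 1]
            area = (r1 - r0) * (c1 - c0)
            cnt = block(sum_m, r0, r1, c0, c1)
            if cnt / area >= MIN_CELL_COVERAGE:
                cells[i, j] = block(sum_t, r0, r1, c0, c1) / cnt
    return HeatMap(cells, label=label, session_id=session_id)


def select_set_heatmaps(
    recording: SessionRecording,
    n_rows: int = DEFAULT_GRID[0],
    n_cols: int = DEFAULT_GRID[1],
    kernel: tuple[int, int] = (3, 3),
) -> HeatMapSet:
    """Heat maps at the beginning and end of each set of a recording.

    Start-of-set frames are the first frame at or after the protocol time;
    end-of-set frames the last frame at or before it.  Each chosen frame is
    aligned, smoothed, segmented and cropped before gridding.
    """
    ts = recording.timestamps
    maps: dict[str, HeatMap] = {}
    for label, t in frame_times(recording.protocol):
        if label.startswith("S"):
            idx = int(np.searchsorted(ts, t, side="left"))
            if idx >= len(ts):
                raise TimelineError(f"no frame at or after t={t} s for {label}")
        else:
            idx = int(np.searchsorted(ts, t, side="right")) - 1
            if idx < 0:
                raise TimelineError(f"no frame at or before t={t} s for {label}")
        roi, roi_mask = preprocess_frame(
            recording.frames[idx], recording.protocol.arm_side, kernel=kernel
        )
        maps[label] = make_heatmap(
            roi, roi_mask, n_rows, n_cols, label=label, session_id=recording.session_id
        )
    return HeatMapSet(maps)


def diff_heatmap(hm_set: HeatMapSet, pair: tuple[str, str]) -> DifferenceHeatMap:
    """Cellwise later-minus-earlier difference for a labeled pair.

    ``pair = (earlier, later)``; e.g. ``("S1", "E3")`` yields E3 − S1, so
    heating is positive.  Missing wherever either operand is missing.
    """
    earlier, later = pair
    for lab in pair:
        if lab not in hm_set.maps:
            raise ThermArmError(f"label {lab!r} not in heat-map set {hm_set.labels}")
    cells = hm_set[later].cells - hm_set[earlier].cells
    return DifferenceHeatMap(cells, pair=(earlier, later), session_id=hm_set.session_id)


def region_means(hm: HeatMap | DifferenceHeatMap) -> RegionSummary:
    """Mean over the deltoid / biceps / triceps regions of a grid.

    Upper half → deltoid; lower-left quadrant → biceps; lower-right
    quadrant → triceps.  Missing cells are excluded; a region with no
    non-missing cells raises :class:`RegionUndefinedError`.
    """
    cells = hm.cells
    n_rows, n_cols = cells.shape
    half_r, half_c = n_rows // 2, n_cols // 2
    regions = {
        "deltoid": cells[:half_r, :],
        "biceps": cells[half_r:, :half_c],
        "triceps": cells[half_r:, half_c:],
    }
    out = {}
    for name, block_cells in regions.items():
        valid = ~np.isnan(block_cells)
        if not valid.any():
            raise RegionUndefinedError(f"all cells missing in {name} region")
        out[name] = float(block_cells[valid].mean())
    return RegionSummary(**out)


def pair_score(hm_set: HeatMapSet, target: MuscleClass, pair: tuple[str, str]) -> float:
    """Target-muscle region mean of the pair's difference heat map (Δ°C)."""
    target = MuscleClass(target)
    if target is MuscleClass.VAGUE:
        raise ThermArmError("pair_score requires a concrete target muscle")
    return region_means(diff_heatmap(hm_set, pair))[target]


def best_pair(hm_set: HeatMapSet, target: MuscleClass, n_sets: int = 3) -> tuple[str, str]:
    """The admissible pair with the largest target-region temperature rise.

    Ties are broken toward the later pair (E3 > S3 > E2 > S2 > E1).
    """
    best = None
    best_score = -np.inf
    for pair in pair_labels(n_sets):
        score = pair_score(hm_set, target, pair)
        if score >= best_score:  # later pairs override on ties
            best, best_score = pair, score
    return best


def pair_rank_table(
    sessions: list[tuple[HeatMapSet, MuscleClass]], n_sets: int = 3
) -> dict[str, dict[str, int]]:
    """Count, per pair, how often it yields the session's highest difference.

    Returns ``{pair_name: {"count": c, "percent": floor(c / total * 100)}}``
    over all admissible pairs.  Percentages use the floor rule.
    """
    if not sessions:
        raise ThermArmError("pair_rank_table needs at least one session")
    counts = {f"{a}-{b}": 0 for a, b in pair_labels(n_sets)}
    for hm_set, target in sessions:
        a, b = best_pair(hm_set, target, n_sets)
        counts[f"{a}-{b}"] += 1
    total = len(sessions)
    return {
        name: {"count": c, "percent": int(np.floor(c / total * 100))}
        for name, c in counts.items()
    }


def first_third_share_percent(counts: dict[str, int]) -> int:
    """Share (floor %) of sessions whose best pair spans the first and third set.

    With the standard pairs these are (S1,S3) and (S1,E3).
    """
    total = sum(counts.values())
    first_third = counts.get("S1-S3", 0) + counts.get("S1-E3", 0)
    return int(np.floor(first_third / total * 100))


def save_heatmap_png(
    hm: HeatMap | DifferenceHeatMap,
    path: str | Path,
    vmin: float | None = None,
    vmax: float | None = None,
) -> Path:
    """Colorized PNG export (inferno colormap, fixed scale if given).

    Visualization only; PNG output is never re-ingested by the pipeline.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    fig, ax = plt.subplots(figsize=(2.4, 6))
    im = ax.imshow(hm.cells, cmap="inferno", vmin=vmin, vmax=vmax)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, label="°C")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path
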
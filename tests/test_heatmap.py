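import numpy as np
import pytest

from thermarm.benchmark import study_config
from thermarm.errors import RegionUndefinedError, ResolutionError, ThermArmError
from thermarm.heatmap import (
    DifferenceHeatMap,
    HeatMap,
    HeatMapSet,
    best_pair,
    diff_heatmap,
    first_third_share_percent,
    make_heatmap,
    pair_rank_table,
    pair_score,
    region_means,
    select_set_heatmaps,
)
from thermarm.preprocess import ArmMask
from thermarm.protocol import MuscleClass, SessionProtocol
from thermarm.simulate import simulate_session
from thermarm.thermal_io import ThermalFrame


def full_mask(shape):
    return ArmMask(np.ones(shape, bool))


def make_set(region_values: dict[str, tuple[float, float, float]]) -> HeatMapSet:
    """Hand-built 60x20 heat-map set with constant (deltoid, biceps, triceps)."""
    maps = {}
    for label, (d, b, t) in region_values.items():
        cells = np.empty((60, 20))
        cells[:30, :] = d
        cells[30:, :10] = b
        cells[30:, 10:] = t
        maps[label] = HeatMap(cells, label=label, session_id="hand")
    return HeatMapSet(maps)


class TestMakeHeatmap:
    def test_constant_fully_masked_roi(self):
        frame = ThermalFrame(np.full((120, 40), 36.0))
        hm = make_heatmap(frame, full_mask((120, 40)))
        assert hm.shape == (60, 20)
        np.testing.assert_allclose(hm.cells, 36.0)
        assert not np.isnan(hm.cells).any()

    def test_cells_equal_bruteforce_block_means(self, rng):
        arr = rng.uniform(25, 40, (120, 40))
        hm = make_heatmap(ThermalFrame(arr), full_mask((120, 40)), n_rows=2, n_cols=2)
        for i in range(2):
            for j in range(2):
                block = arr[60 * i : 60 * (i + 1), 20 * j : 20 * (j + 1)]
                assert hm.cells[i, j] == pytest.approx(block.mean(), rel=1e-12)

    def test_random_rois_match_enumeration_oracle(self, rng):
        """Every cell equals the mean over its explicitly enumerated masked
        pixels, on ROIs whose size does not divide the grid evenly."""
        for _ in range(5):
            h = int(rng.integers(61, 130))
            w = int(rng.integers(21, 50))
            arr = rng.uniform(25, 40, (h, w))
            mask = rng.random((h, w)) < 0.8
            mask[0, 0] = True
            hm = make_heatmap(ThermalFrame(arr), ArmMask(mask))
            redges = np.floor(np.arange(61) * h / 60).astype(int)
            cedges = np.floor(np.arange(21) * w / 20).astype(int)
            for i in range(60):
                for j in range(20):
                    sub = np.s_[redges[i] : redges[i + 1], cedges[j] : cedges[j + 1]]
                    pix, msk = arr[sub], mask[sub]
                    if msk.mean() >= 0.5:
                        assert hm.cells[i, j] == pytest.approx(pix[msk].mean(), rel=1e-12)
                    else:
                        assert np.isnan(hm.cells[i, j])

    def test_unmasked_cell_is_missing(self):
        mask = np.ones((120, 40), bool)
        mask[:2, :2] = False  # first 2x2-px cell fully outside the mask
        hm = make_heatmap(ThermalFrame(np.full((120, 40), 30.0)), ArmMask(mask))
        assert np.isnan(hm.cells[0, 0])
        assert np.isfinite(hm.cells[5, 5])

    def test_roi_smaller_than_grid_rejected(self):
        with pytest.raises(ResolutionError):
            make_heatmap(ThermalFrame(np.full((30, 10), 30.0)), full_mask((30, 10)))


class TestSelect:
    def test_three_set_session_yields_six_maps(self, noiseless_heatmaps):
        assert sorted(noiseless_heatmaps.labels) == ["E1", "E2", "E3", "S1", "S2", "S3"]

    def test_one_set_session_yields_two_maps(self):
        protocol = SessionProtocol(
            n_sets=1, reps_per_set=15, recovery_s=300, target_muscle=MuscleClass.BICEPS
        )
        cfg = study_config(MuscleClass.BICEPS, seed=0, noise_sd=0.0)
        hm_set = select_set_heatmaps(simulate_session(protocol, cfg))
        assert sorted(hm_set.labels) == ["E1", "S1"]


class TestDiff:
    def test_self_difference_is_zero(self, noiseless_heatmaps):
        d = diff_heatmap(noiseless_heatmaps, ("S1", "S1"))
        valid = ~np.isnan(d.cells)
        np.testing.assert_allclose(d.cells[valid], 0.0)

    def test_orientation_later_minus_earlier(self):
        hm_set = make_set({"S1": (36.0, 36.0, 36.0), "E3": (36.9, 36.9, 36.9)})
        d = diff_heatmap(hm_set, ("S1", "E3"))
        np.testing.assert_allclose(d.cells, 0.9)

    def test_telescoping_additivity(self, noiseless_heatmaps):
        a = diff_heatmap(noiseless_heatmaps, ("S1", "S3")).cells
        b = diff_heatmap(noiseless_heatmaps, ("S3", "E3")).cells
        c = diff_heatmap(noiseless_heatmaps, ("S1", "E3")).cells
        valid = ~np.isnan(c)
        np.testing.assert_allclose((a + b)[valid], c[valid], atol=1e-9)

    def test_unknown_label_rejected(self, noiseless_heatmaps):
        with pytest.raises(ThermArmError):
            diff_heatmap(noiseless_heatmaps, ("S1", "E9"))


class TestRegionMeans:
    def test_constant_regions(self):
        hm_set = make_set({"S1": (37.0, 36.0, 35.0)})
        rs = region_means(hm_set["S1"])
        assert (rs.deltoid, rs.biceps, rs.triceps) == (37.0, 36.0, 35.0)

    def test_matches_index_enumeration_oracle(self, rng):
        for _ in range(100):
            cells = rng.uniform(25, 40, (60, 20))
            cells[rng.random((60, 20)) < 0.1] = np.nan
            hm = HeatMap(cells)
            try:
                rs = region_means(hm)
            except RegionUndefinedError:
                continue
            regions = {"deltoid": [], "biceps": [], "triceps": []}
            for i in range(60):
                for j in range(20):
                    if np.isnan(cells[i, j]):
                        continue
                    if i < 30:
                        regions["deltoid"].append(cells[i, j])
                    elif j < 10:
                        regions["biceps"].append(cells[i, j])
                    else:
                        regions["triceps"].append(cells[i, j])
            assert rs.deltoid == pytest.approx(np.mean(regions["deltoid"]), rel=1e-12)
            assert rs.biceps == pytest.approx(np.mean(regions["biceps"]), rel=1e-12)
            assert rs.triceps == pytest.approx(np.mean(regions["triceps"]), rel=1e-12)

    def test_all_missing_region_rejected(self):
        cells = np.full((60, 20), 30.0)
        cells[:30, :] = np.nan
        with pytest.raises(RegionUndefinedError):
            region_means(HeatMap(cells))


class TestPairScore:
    def test_hand_built_scores(self):
        hm_set = make_set(
            {
                "S1": (36.0, 36.0, 36.0),
                "E1": (36.1, 36.2, 36.1),
                "S2": (36.2, 36.5, 36.2),
                "E2": (36.3, 36.6, 36.3),
                "S3": (36.4, 36.9, 36.4),
                "E3": (36.5, 37.0, 36.5),
            }
        )
        assert pair_score(hm_set, MuscleClass.BICEPS, ("S1", "E3")) == pytest.approx(1.0)
        assert pair_score(hm_set, MuscleClass.BICEPS, ("S1", "S2")) == pytest.approx(0.5)
        assert pair_score(hm_set, MuscleClass.DELTOID, ("S1", "E3")) == pytest.approx(0.5)

    def test_monotone_session_prefers_final_pair(self, noiseless_heatmaps):
        scores = {
            pair: pair_score(noiseless_heatmaps, MuscleClass.BICEPS, pair)
            for pair in [("S1", "E1"), ("S1", "S2"), ("S1", "E2"), ("S1", "S3"), ("S1", "E3")]
        }
        assert max(scores, key=scores.get) == ("S1", "E3")

    def test_zero_dynamics_zero_scores(self):
        hm_set = make_set({lab: (36.0, 36.0, 36.0) for lab in ["S1", "E1", "S2", "E2", "S3", "E3"]})
        for pair in [("S1", "E1"), ("S1", "E3")]:
            assert pair_score(hm_set, MuscleClass.TRICEPS, pair) == 0.0


class TestPairRanking:
    def test_single_session(self, noiseless_heatmaps):
        table = pair_rank_table([(noiseless_heatmaps, MuscleClass.BICEPS)])
        assert table["S1-E3"] == {"count": 1, "percent": 100}

    def test_ties_broken_toward_later_pair(self):
        hm_set = make_set({lab: (36.0, 36.0, 36.0) for lab in ["S1", "E1", "S2", "E2", "S3", "E3"]})
        assert best_pair(hm_set, MuscleClass.BICEPS) == ("S1", "E3")

    def test_floor_percentages(self, noiseless_heatmaps):
        sessions = [(noiseless_heatmaps, MuscleClass.BICEPS)] * 7
        table = pair_rank_table(sessions)
        assert table["S1-E3"]["percent"] == 100
        assert sum(v["count"] for v in table.values()) == 7

    def test_first_third_share_of_printed_counts(self):
        # the study's observed distribution of best pairs over 70 sessions
        counts = {"S1-E3": 36, "S1-S3": 24, "S1-E2": 4, "S1-S2": 2, "S1-E1": 4}
        assert first_third_share_percent(counts) == 85

    def test_empty_session_list_rejected(self):
        with pytest.raises(ThermArmError):
            pair_rank_table([])
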
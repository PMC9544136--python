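"""Hot-spot procedure: downsampling, neighbor counting, center selection, disc stats."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phoxspot import (
    HotspotParams,
    NoHotspot,
    PlantedCluster,
    SimulationConfig,
    count_positive_neighbors,
    downsample,
    find_hotspot,
    generate_slide,
    hotspot_statistics,
    overall_positivity,
    select_center,
)
from phoxspot.errors import EmptyInputError, ParameterError
from conftest import brute_force_neighbor_counts, make_cells


def random_cells(n, seed, extent=2000.0, p=0.5):
    rng = np.random.default_rng(seed)
    return make_cells(rng.uniform(0, extent, n), rng.uniform(0, extent, n),
                      rng.random(n) < p)


class TestDownsample:
    def test_factor_one_is_identity(self):
        cells = random_cells(50, 0)
        assert downsample(cells, 1, seed=123) is cells

    def test_size_and_id_contract(self):
        cells = random_cells(100, 1)
        sub = downsample(cells, 4, seed=0)
        assert len(sub) == 25
        assert len(set(sub.cell_id)) == 25
        assert set(sub.cell_id) <= set(cells.cell_id)
        assert np.all(np.diff(sub.cell_id) > 0)  # relative order preserved

    def test_ceiling_size(self):
        assert len(downsample(random_cells(10, 2), 3)) == 4  # ceil(10/3)

    def test_seed_determinism_and_sensitivity(self):
        cells = random_cells(1000, 3)
        a = downsample(cells, 4, seed=1)
        b = downsample(cells, 4, seed=1)
        c = downsample(cells, 4, seed=2)
        np.testing.assert_array_equal(a.cell_id, b.cell_id)
        assert not np.array_equal(a.cell_id, c.cell_id)

    def test_systematic_mode(self):
        cells = random_cells(10, 4)
        sub = downsample(cells, 3, mode="systematic")
        np.testing.assert_array_equal(sub.cell_id, [0, 3, 6, 9])

    def test_invalid_factor(self):
        with pytest.raises(ParameterError):
            downsample(random_cells(10, 5), 0)


class TestCountPositiveNeighbors:
    def test_single_positive_cell_has_zero_neighbors(self):
        cells = make_cells([10.0], [10.0], [True])
        assert count_positive_neighbors(cells, 500.0) == [(0, 0)]

    def test_collinear_triple(self):
        # Positives at x = 0, 400, 800 with radius 500: ends see only the
        # middle cell, the middle sees both.
        cells = make_cells([0.0, 400.0, 800.0], [0.0, 0.0, 0.0], [True] * 3)
        assert count_positive_neighbors(cells, 500.0) == [(0, 1), (1, 2), (2, 1)]
        assert select_center(count_positive_neighbors(cells, 500.0)) == 1

    def test_distance_exactly_at_radius_counts(self):
        cells = make_cells([0.0, 500.0], [0.0, 0.0], [True, True])
        assert count_positive_neighbors(cells, 500.0) == [(0, 1), (1, 1)]

    def test_negative_cells_ignored(self):
        cells = make_cells([0.0, 10.0, 20.0], [0.0, 0.0, 0.0], [True, False, True])
        assert count_positive_neighbors(cells, 500.0) == [(0, 1), (2, 1)]

    def test_no_positive_cells_gives_empty_list(self):
        cells = make_cells([0.0, 1.0], [0.0, 1.0], [False, False])
        assert count_positive_neighbors(cells, 500.0) == []

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_quadratic_oracle(self, seed):
        cells = random_cells(500, seed, extent=3000.0, p=0.3)
        assert count_positive_neighbors(cells, 500.0) == \
            brute_force_neighbor_counts(cells, 500.0)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_oracle_equivalence_property(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 120))
        radius = float(rng.uniform(10.0, 800.0))
        cells = make_cells(rng.uniform(0, 1000, n), rng.uniform(0, 1000, n),
                           rng.random(n) < 0.5)
        assert count_positive_neighbors(cells, radius) == \
            brute_force_neighbor_counts(cells, radius)


class TestSelectCenter:
    def test_singleton(self):
        assert select_center([(5, 0)]) == 5

    def test_tie_broken_by_smallest_id(self):
        assert select_center([(1, 3), (2, 3), (9, 2)]) == 1
        assert select_center([(9, 3), (2, 3), (1, 2)]) == 2

    def test_empty_is_error(self):
        with pytest.raises(EmptyInputError):
            select_center([])


class TestHotspotStatistics:
    def test_disc_containing_only_the_center(self):
        cells = make_cells([0.0, 5000.0], [0.0, 0.0], [True, True])
        n_pos, n_total, percent = hotspot_statistics(cells, (0.0, 0.0), 500.0)
        assert (n_pos, n_total, percent) == (1, 1, 100.0)

    def test_direct_ratio(self):
        # 2 positive + 8 negative inside the disc, plus distant cells outside.
        x = np.concatenate([np.linspace(0, 400, 10), [5000.0, 6000.0]])
        labels = [True, True] + [False] * 8 + [True, True]
        cells = make_cells(x, np.zeros_like(x), labels)
        n_pos, n_total, percent = hotspot_statistics(cells, (0.0, 0.0), 500.0)
        assert (n_pos, n_total) == (2, 10)
        assert percent == pytest.approx(20.0)

    def test_adding_positive_cell_in_disc_never_decreases_count(self):
        cells = random_cells(300, 8, extent=1500.0, p=0.3)
        center = (750.0, 750.0)
        before = hotspot_statistics(cells, center, 500.0)
        augmented = make_cells(np.append(cells.x, 760.0), np.append(cells.y, 760.0),
                               np.append(cells.positive, True))
        after = hotspot_statistics(augmented, center, 500.0)
        assert after[0] == before[0] + 1


class TestFindHotspot:
    def test_below_threshold_gives_reasoned_no_hotspot(self):
        cells = random_cells(5000, 9, p=0.0001)  # ~0.01% positive
        assert overall_positivity(cells) < 0.05
        outcome = find_hotspot(cells, HotspotParams())
        assert isinstance(outcome, NoHotspot)
        assert not outcome
        assert outcome.reason == "below eligibility threshold"

    def test_exactly_at_threshold_is_ineligible(self):
        # 1 positive of 2000 cells = 0.05% exactly: strict "above" rule.
        cells = random_cells(2000, 10, p=0.0)
        cells.positive[0] = True
        assert overall_positivity(cells) == pytest.approx(0.05)
        outcome = find_hotspot(cells, HotspotParams())
        assert isinstance(outcome, NoHotspot)

    def test_all_positive_slide(self):
        cells = random_cells(2000, 11, p=1.0)
        result = find_hotspot(cells, HotspotParams())
        assert result
        assert result.percent_positive == 100.0
        assert result.n_positive_in_disc == result.n_total_in_disc >= 1

    def test_empty_table_is_error(self):
        with pytest.raises(EmptyInputError):
            find_hotspot(make_cells([], [], []), HotspotParams())

    def test_center_is_a_positive_cell_with_maximal_count(self):
        cells = random_cells(3000, 12, extent=3000.0, p=0.2)
        params = HotspotParams(downsample_factor=4, downsample_seed=5)
        result = find_hotspot(cells, params)
        sub = downsample(cells, 4, seed=5)
        counts = dict(count_positive_neighbors(sub, params.neighbor_radius))
        assert result.center_cell_id in counts
        assert counts[result.center_cell_id] == max(counts.values())
        assert result.neighbor_count_at_center == counts[result.center_cell_id]

    def test_determinism(self, clustered_slide):
        cells, _, _ = clustered_slide
        params = HotspotParams()
        assert find_hotspot(cells, params) == find_hotspot(cells, params)

    def test_stats_on_downsampled_mode(self, clustered_slide):
        cells, _, _ = clustered_slide
        full = find_hotspot(cells, HotspotParams(stats_on="full"))
        sub = find_hotspot(cells, HotspotParams(stats_on="downsampled"))
        assert sub.center_cell_id == full.center_cell_id
        assert sub.n_total_in_disc < full.n_total_in_disc

    def test_planted_cluster_recovery_across_downsample_factors(self):
        # Strongly clustered slides: centers found with factor 1 and factor 4
        # agree with each other and with the planted center (within 300 um)
        # in at least 18 of 20 seeds.
        hits_truth = hits_agree = 0
        for seed in range(20):
            cfg = SimulationConfig(
                clusters=[PlantedCluster((5000.0, 5000.0), 500.0, 0.30)], seed=seed
            )
            cells, _ = generate_slide(cfg)
            r4 = find_hotspot(cells, HotspotParams(downsample_factor=4))
            r1 = find_hotspot(cells, HotspotParams(downsample_factor=1))
            d4 = np.hypot(r4.center_xy[0] - 5000.0, r4.center_xy[1] - 5000.0)
            d1 = np.hypot(r1.center_xy[0] - 5000.0, r1.center_xy[1] - 5000.0)
            dd = np.hypot(r4.center_xy[0] - r1.center_xy[0],
                          r4.center_xy[1] - r1.center_xy[1])
            hits_truth += (d4 <= 300.0) and (d1 <= 300.0)
            hits_agree += dd <= 300.0
        assert hits_truth >= 18
        assert hits_agree >= 18

    def test_uniform_slide_hotspot_tracks_overall_in_expectation(self):
        # On uniformly labeled slides the hot spot is pure noise: the mean
        # selected-disc percentage must stay within 4 binomial standard errors
        # (one disc's worth) of the overall percentage. The argmax selection
        # introduces a small upward bias, well inside that band.
        diffs, n_disc = [], None
        for seed in range(20):
            cfg = SimulationConfig(slide_width=4.0, slide_height=4.0,
                                   baseline_positive_fraction=0.3, seed=seed)
            cells, _ = generate_slide(cfg)
            result = find_hotspot(cells, HotspotParams())
            diffs.append(result.percent_positive - overall_positivity(cells))
            n_disc = result.n_total_in_disc
        se_percent = 100.0 * np.sqrt(0.3 * 0.7 / n_disc)
        assert abs(np.mean(diffs)) <= 4 * se_percent

    def test_result_fields_are_consistent(self, clustered_slide):
        cells, _, _ = clustered_slide
        result = find_hotspot(cells, HotspotParams())
        assert 1 <= result.n_positive_in_disc <= result.n_total_in_disc
        assert result.percent_positive == pytest.approx(
            100.0 * result.n_positive_in_disc / result.n_total_in_disc)
        assert result.radius == 500.0
        assert dataclasses.asdict(result)  # serializable
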
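import numpy as np
import pytest

import adfield as a

from conftest import grid_table


@pytest.fixture
def strip5():
    return a.build_domain(grid_table([(i, 0) for i in range(5)]))


@pytest.fixture
def two_region_strip():
    return a.build_domain(
        grid_table([(i, 0) for i in range(10)], ecoregion=[0] * 5 + [1] * 5)
    )


class TestSpread:
    def test_size_one_is_the_start(self, strip5):
        r = a.spread(strip5, 1, np.random.default_rng(0), start=3)
        assert r.cells.tolist() == [3]

    def test_size_N_fills_the_domain(self, strip5):
        r = a.spread(strip5, 5, np.random.default_rng(0), start=2)
        assert r.cells.tolist() == [0, 1, 2, 3, 4]

    def test_strip_growth_from_end_is_deterministic(self, strip5):
        # only one frontier cell exists at each step
        r = a.spread(strip5, 3, np.random.default_rng(0), start=0)
        assert r.cells.tolist() == [0, 1, 2]

    def test_invalid_size_rejected(self, strip5):
        for bad in (0, 6):
            with pytest.raises(a.ValidationError):
                a.spread(strip5, bad, np.random.default_rng(0))

    def test_exhausted_component_errors_after_retries(self):
        dom = a.build_domain(grid_table([(0, 0), (5, 5)]))
        with pytest.raises(a.InfeasibleSimulationError):
            a.spread(dom, 2, np.random.default_rng(0), max_retries=3)

    @pytest.mark.parametrize("sampling", ["frontier", "neighbor_of_cell"])
    @pytest.mark.parametrize("mode", ["rook", "queen"])
    def test_ranges_connected_and_exactly_sized(self, sampling, mode):
        dom = a.make_domain("disc", 120, adjacency_mode=mode)
        rng = np.random.default_rng(1)
        for _ in range(300):
            size = int(rng.integers(1, 30))
            r = a.null_range(dom, size, rng, sampling=sampling)
            assert len(r.cells) == size
            assert a.is_connected(dom, r.cells)
            assert np.all((0 <= r.cells) & (r.cells < dom.n_cells))


class TestNullRange:
    def test_start_cells_uniform(self):
        dom = a.make_domain("rectangle", 16)
        rng = np.random.default_rng(2)
        starts = [a.null_range(dom, 1, rng).start for _ in range(4000)]
        counts = np.bincount(starts, minlength=16)
        from scipy.stats import chisquare

        assert chisquare(counts).pvalue > 0.01


class TestEnergyModel:
    def test_requires_energy_layer(self, strip5):
        with pytest.raises(a.ValidationError, match="energy"):
            a.energy_model_range(strip5, 2, np.random.default_rng(0))

    def test_degenerate_energy_fixes_the_seed(self):
        dom = a.make_domain("rectangle", 9)
        dom.energy = np.zeros(9)
        dom.energy[4] = 1.0
        rng = np.random.default_rng(3)
        for _ in range(50):
            assert a.energy_model_range(dom, 3, rng).start == 4

    def test_all_zero_energy_rejected(self):
        dom = a.make_domain("rectangle", 9)
        dom.energy = np.zeros(9)
        with pytest.raises(a.ValidationError, match="zero"):
            a.energy_model_range(dom, 2, np.random.default_rng(0))

    def test_three_to_one_energy_seed_frequencies(self):
        dom = a.build_domain(grid_table([(0, 0), (1, 0)], energy=[3.0, 1.0]))
        rng = np.random.default_rng(4)
        starts = np.array(
            [a.energy_model_range(dom, 1, rng).start for _ in range(10000)]
        )
        freq = (starts == 0).mean()
        assert freq == pytest.approx(0.75, abs=0.02)  # ~5 sigma of binomial


class TestEcoregionModel:
    def test_requires_layer_and_sane_penalty(self, strip5, two_region_strip):
        rng = np.random.default_rng(0)
        with pytest.raises(a.ValidationError, match="ecoregion"):
            a.ecoregion_model_range(strip5, 2, rng)
        with pytest.raises(a.ValidationError, match="penalty"):
            a.ecoregion_model_range(two_region_strip, 2, rng, penalty=0.5)

    def test_zero_occupancy_rejected(self, two_region_strip):
        with pytest.raises(a.ValidationError, match="occupancy"):
            a.ecoregion_model_range(
                two_region_strip, 2, np.random.default_rng(0),
                species_occupancy={0: 0.0, 1: 0.0},
            )

    def test_infinite_penalty_confines_range_to_home_region(self, two_region_strip):
        rng = np.random.default_rng(5)
        for _ in range(100):
            r = a.ecoregion_model_range(
                two_region_strip, 4, rng, penalty=np.inf
            )
            labels = set(two_region_strip.ecoregion[r.cells])
            assert len(labels) == 1

    def test_forced_crossing_spans_both_regions(self):
        dom = a.build_domain(grid_table([(0, 0), (1, 0)], ecoregion=[0, 1]))
        rng = np.random.default_rng(6)
        r = a.ecoregion_model_range(dom, 2, rng, penalty=30.0)
        assert r.cells.tolist() == [0, 1]

    def test_penalty_one_is_unconstrained(self, two_region_strip):
        rng = np.random.default_rng(7)
        crossed = sum(
            len(set(two_region_strip.ecoregion[
                a.ecoregion_model_range(two_region_strip, 6, rng, penalty=1.0).cells
            ])) == 2
            for _ in range(200)
        )
        assert crossed > 50  # crossing frequent when unpenalised

    def test_seed_region_follows_occupancy_weights(self, two_region_strip):
        rng = np.random.default_rng(8)
        homes = [
            int(two_region_strip.ecoregion[
                a.ecoregion_model_range(
                    two_region_strip, 1, rng, species_occupancy={0: 1.0, 1: 0.0}
                ).start
            ])
            for _ in range(50)
        ]
        assert set(homes) == {0}


class TestRichnessConstrainedAssembly:
    def test_single_species_covers_its_targets(self, strip5):
        target = np.array([1, 1, 1, 0, 0])
        ranges = a.richness_constrained_assembly(
            strip5, [3], target, np.random.default_rng(0)
        )
        assert ranges[0].cells.tolist() == [0, 1, 2]

    def test_two_species_tile_a_strip(self):
        dom = a.build_domain(grid_table([(i, 0) for i in range(4)]))
        rng = np.random.default_rng(1)
        for _ in range(20):
            ranges = a.richness_constrained_assembly(
                dom, [2, 2], np.array([1, 1, 1, 1]), rng
            )
            cells = sorted(c for r in ranges for c in r.cells)
            assert cells == [0, 1, 2, 3]
            # both valid tilings are pairs of adjacent cells
            for r in ranges:
                assert a.is_connected(dom, r.cells)

    def test_realized_richness_equals_target_exactly(self):
        dom = a.make_domain("rectangle", 36)
        rng = np.random.default_rng(2)
        for run in range(20):
            ref, _ = a.simulate_fauna(
                dom, [5, 3, 7, 2, 4], model="null",
                rng=np.random.default_rng(100 + run),
            )
            ranges = a.richness_constrained_assembly(
                dom, [5, 3, 7, 2, 4], ref.richness, rng
            )
            got = np.zeros(36, dtype=int)
            for r in ranges:
                got[r.cells] += 1
            assert np.array_equal(got, ref.richness)

    def test_incidence_conservation_precondition(self, strip5):
        with pytest.raises(a.ValidationError, match="must equal"):
            a.richness_constrained_assembly(
                strip5, [3], np.array([1, 1, 0, 0, 0]), np.random.default_rng(0)
            )

    def test_small_gaps_allowed_within_ladder(self, strip5):
        # deficit cells 0 and 2 only: the range must jump the gap at 1
        target = np.array([1, 0, 1, 0, 0])
        ranges = a.richness_constrained_assembly(
            strip5, [2], target, np.random.default_rng(3)
        )
        assert ranges[0].cells.tolist() == [0, 2]

    def test_gap_beyond_ladder_is_infeasible(self):
        dom = a.build_domain(grid_table([(i, 0) for i in range(7)]))
        target = np.array([1, 0, 0, 0, 0, 0, 1])
        with pytest.raises(a.InfeasibleSimulationError, match="stalled"):
            a.richness_constrained_assembly(
                dom, [2], target, np.random.default_rng(4), max_restarts=3
            )


class TestSimulateFauna:
    def test_cosmopolitan_null_fauna_is_all_ones(self, strip5):
        P, _ = a.simulate_fauna(strip5, [5, 5], rng=np.random.default_rng(0))
        assert P.matrix.toarray().tolist() == [[1] * 5, [1] * 5]

    def test_row_sums_match_requested_sizes(self):
        dom = a.make_domain("disc", 80)
        sizes = [1, 4, 9, 16, 25]
        P, manifest = a.simulate_fauna(dom, sizes, rng=np.random.default_rng(1))
        assert P.range_sizes.tolist() == sizes
        assert [s["size"] for s in manifest["species"]] == sizes

    def test_same_seed_bit_identical(self):
        dom = a.make_domain("disc", 80)
        cfg = a.AssemblyConfig(seed=9)
        P1, _ = a.simulate_fauna(dom, [3, 6, 9], config=cfg)
        P2, _ = a.simulate_fauna(dom, [3, 6, 9], config=cfg)
        assert (P1.matrix != P2.matrix).nnz == 0

    def test_manifest_records_ground_truth(self, two_region_strip):
        P, manifest = a.simulate_fauna(
            two_region_strip, [3, 3], model="ecoregion",
            config=a.AssemblyConfig(seed=2, boundary_penalty=30.0),
        )
        assert manifest["model"] == "ecoregion"
        assert manifest["boundary_penalty"] == 30.0
        for entry in manifest["species"]:
            assert "home_ecoregion" in entry and "start" in entry
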
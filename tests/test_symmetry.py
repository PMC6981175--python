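import numpy as np
import pytest

import adfield as a

from conftest import grid_table, random_presence


def transcription_centroids(m, centers):
    """Literal per-species mean-coordinate formulas; the oracle."""
    S, N = m.shape
    out = np.zeros((S, 2))
    for i in range(S):
        r = sum(m[i, j] for j in range(N))
        out[i, 0] = sum(m[i, j] * centers[j, 0] for j in range(N)) / r
        out[i, 1] = sum(m[i, j] * centers[j, 1] for j in range(N)) / r
    return out


def transcription_cog(m, centers, j):
    """Literal mean-of-species-centroids center of gravity; the oracle."""
    cent = transcription_centroids(m, centers)
    s = sum(m[i, j] for i in range(m.shape[0]))
    x = sum(m[i, j] * cent[i, 0] for i in range(m.shape[0])) / s
    y = sum(m[i, j] * cent[i, 1] for i in range(m.shape[0])) / s
    return x, y


class TestSpeciesCentroid:
    def test_two_cell_range_midpoint(self, strip_domain, toy_P):
        assert a.species_centroid(toy_P, strip_domain, 0) == (1.0, 0.5)

    def test_single_cell_range_is_that_center(self, strip_domain, toy_P):
        assert a.species_centroid(toy_P, strip_domain, 2) == (1.5, 0.5)

    def test_3x3_block_range_centers_on_block(self, block3x3):
        P = a.PresenceAbsence.from_dense(np.ones((1, 9), dtype=int))
        assert a.species_centroid(P, block3x3, 0) == (1.5, 1.5)

    def test_out_of_range_species_errors(self, strip_domain, toy_P):
        with pytest.raises(a.ValidationError):
            a.species_centroid(toy_P, strip_domain, 5)


class TestUntrimmedCenterOfGravity:
    def test_toy_focal_B_hand_arithmetic(self, strip_domain, toy_P):
        # species centroids x: sp1 -> 1.0, sp2 -> 2.0, sp3 -> 1.5; mean 1.5
        x, y = a.untrimmed_center_of_gravity(toy_P, strip_domain, 1)
        assert (x, y) == pytest.approx((1.5, 0.5))

    def test_symmetric_ranges_give_focal_center(self, strip_domain):
        # both species' ranges symmetric about B
        P = a.PresenceAbsence.from_dense(np.array([[1, 1, 1], [0, 1, 0]]))
        assert a.untrimmed_center_of_gravity(P, strip_domain, 1) == \
            pytest.approx((1.5, 0.5))

    def test_focal_only_species_gives_focal_center(self, strip_domain):
        P = a.PresenceAbsence.from_dense(np.array([[0, 1, 0]]))
        assert a.untrimmed_center_of_gravity(P, strip_domain, 1) == (1.5, 0.5)

    def test_empty_cell_signalled(self, strip_domain):
        P = a.PresenceAbsence.from_dense(np.array([[1, 0, 1]]))
        with pytest.raises(a.ValidationError, match="undefined"):
            a.untrimmed_center_of_gravity(P, strip_domain, 1)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_literal_transcription(self, seed):
        rng = np.random.default_rng(seed)
        m = random_presence(rng, 12, 24)
        side = int(np.ceil(np.sqrt(m.shape[1])))
        pos = [(i, j) for i in range(side) for j in range(side)][: m.shape[1]]
        dom = a.build_domain(grid_table(pos))
        P = a.PresenceAbsence.from_dense(m)
        assert np.allclose(
            a.species_centroids(P, dom),
            transcription_centroids(m, dom.centers),
            rtol=0, atol=1e-12,
        )
        for j in range(m.shape[1]):
            if m[:, j].sum() == 0:
                continue
            assert a.untrimmed_center_of_gravity(P, dom, j) == pytest.approx(
                transcription_cog(m, dom.centers, j), abs=1e-12
            )


class TestTrimming:
    def test_toy_focal_B_cutoff_half_keeps_only_focal(self, toy_P):
        region = a.trim_adf(a.dispersion_field(toy_P, 1), 0.5)
        assert region.cells.tolist() == [1]

    def test_tiny_cutoff_keeps_every_sharing_cell(self, toy_P):
        region = a.trim_adf(a.dispersion_field(toy_P, 1), 1e-9)
        assert region.cells.tolist() == [0, 1, 2]

    def test_cutoff_one_keeps_cells_sharing_whole_assemblage(self, toy_P):
        region = a.trim_adf(a.dispersion_field(toy_P, 0), 1.0)
        assert region.cells.tolist() == [0, 1]  # B shares both of A's species

    @pytest.mark.parametrize("bad", [0.0, -0.2, 1.5])
    def test_cutoff_outside_unit_interval_rejected(self, toy_P, bad):
        with pytest.raises(a.ValidationError, match="cutoff"):
            a.trim_adf(a.dispersion_field(toy_P, 1), bad)

    @pytest.mark.parametrize("mode", ["focal_richness", "max_offfocal"])
    @pytest.mark.parametrize("seed", range(4))
    def test_monotone_in_cutoff(self, seed, mode):
        """Raising the cutoff can only shrink the central region."""
        m = random_presence(np.random.default_rng(300 + seed), 15, 30)
        P = a.PresenceAbsence.from_dense(m)
        for j in range(m.shape[1]):
            if m[:, j].sum() == 0:
                continue
            f = a.dispersion_field(P, j)
            prev = None
            for c in (0.1, 0.3, 0.5, 0.7, 0.9, 1.0):
                cells = set(a.trim_adf(f, c, cutoff_mode=mode).cells)
                if prev is not None:
                    assert cells <= prev
                prev = cells

    def test_focal_cell_always_retained(self, toy_P):
        for mode in ("focal_richness", "max_offfocal"):
            for c in (0.3, 1.0):
                region = a.trim_adf(a.dispersion_field(toy_P, 2), c,
                                    cutoff_mode=mode)
                assert 2 in region.cells


class TestAsymmetryVector:
    def test_symmetric_field_has_zero_length(self, strip_domain):
        P = a.PresenceAbsence.from_dense(np.array([[1, 1, 1]]))
        v = a.asymmetry_vector(a.dispersion_field(P, 1), strip_domain, 0.5)
        assert v.length == pytest.approx(0.0)

    def test_toy_focal_B_degenerate_region(self, strip_domain, toy_P):
        v = a.asymmetry_vector(a.dispersion_field(toy_P, 1), strip_domain, 0.5)
        assert (v.dx, v.dy) == (0.0, 0.0) and v.degenerate

    def test_two_cell_weighted_mean_closed_form(self, strip_domain):
        # focal A shares 1 of 2 species with B only: weights 2 (A), 1 (B)
        P = a.PresenceAbsence.from_dense(np.array([[1, 1, 0], [1, 0, 0]]))
        v = a.asymmetry_vector(a.dispersion_field(P, 0), strip_domain, 0.5)
        # cog = (2*(0.5) + 1*(1.5)) / 3; vector = d/3 toward B with d = 1
        assert (v.dx, v.dy) == pytest.approx((1 / 3, 0.0))
        assert v.length == pytest.approx(1 / 3)
        assert v.angle_deg == pytest.approx(0.0)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(17)
        m = (rng.random((10, 16)) < 0.4).astype(int)
        m[m.sum(axis=1) == 0, 0] = 1
        pos = [(i, j) for i in range(4) for j in range(4)]
        t0 = grid_table(pos)
        t1 = t0.assign(lon=t0.lon + 11.0, lat=t0.lat - 3.0)
        P = a.PresenceAbsence.from_dense(m)
        for j in range(16):
            if m[:, j].sum() == 0:
                continue
            f = a.dispersion_field(P, j)
            v0 = a.asymmetry_vector(f, a.build_domain(t0), 0.4)
            v1 = a.asymmetry_vector(f, a.build_domain(t1), 0.4)
            assert (v0.dx, v0.dy) == pytest.approx((v1.dx, v1.dy))
            assert v0.length == pytest.approx(v1.length)

    def test_reflection_equivariance(self):
        rng = np.random.default_rng(18)
        m = (rng.random((10, 16)) < 0.4).astype(int)
        m[m.sum(axis=1) == 0, 0] = 1
        pos = [(i, j) for i in range(4) for j in range(4)]
        t0 = grid_table(pos)
        t1 = t0.assign(lon=-t0.lon)
        P = a.PresenceAbsence.from_dense(m)
        for j in range(16):
            if m[:, j].sum() == 0:
                continue
            f = a.dispersion_field(P, j)
            v0 = a.asymmetry_vector(f, a.build_domain(t0), 0.4)
            v1 = a.asymmetry_vector(f, a.build_domain(t1), 0.4)
            assert v1.dx == pytest.approx(-v0.dx)
            assert v1.dy == pytest.approx(v0.dy)


class TestSymmetryDiagram:
    def test_singleton_fauna_gives_all_zero_vectors(self):
        """One endemic species per cell: every field degenerates to the
        focal cell, so asymmetry vanishes everywhere."""
        dom = a.make_domain("disc", 60)
        P = a.PresenceAbsence.from_dense(np.eye(dom.n_cells, dtype=int))
        d = a.symmetry_diagram(P, dom, 0.5)
        assert np.allclose(d.lengths, 0.0)

    def test_cosmopolitan_fauna_points_at_domain_centroid(self):
        dom = a.make_domain("disc", 60)
        P = a.PresenceAbsence.from_dense(np.ones((1, dom.n_cells), dtype=int))
        d = a.symmetry_diagram(P, dom, 0.5)
        cx, cy = a.domain_centroid(dom)
        for row in d.table.itertuples():
            assert (row.lon + row.dx, row.lat + row.dy) == pytest.approx((cx, cy))

    def test_one_vector_per_nonempty_cell(self, strip_domain):
        P = a.PresenceAbsence.from_dense(np.array([[1, 0, 1]]))
        d = a.symmetry_diagram(P, strip_domain, 0.5)
        assert sorted(d.table.cell_id) == [0, 2]

    def test_histogram_metadata_recorded(self, strip_domain, toy_P):
        d = a.symmetry_diagram(toy_P, strip_domain, 0.5)
        assert d.metadata["histogram_bins"] == 30
        assert len(d.histogram_counts) == 30
        assert d.histogram_counts.sum() == len(d.table)
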
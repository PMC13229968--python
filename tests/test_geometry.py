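"""Forward kinematics, trait derivation and top-view metadata."""

import numpy as np
import pytest

from plantarch import (
    Internode,
    Leaf,
    Petiole,
    Phytomer,
    PlantArchitecture,
    Shoot,
    bounding_metadata,
    count_organs,
    generate_plant,
    leaf_inclination_distribution,
    plant_height,
    reconstruct_geometry,
    tokenize_architecture,
)
from plantarch.model import PlantMetadata, copy_plant
from plantarch.tokenizer import DecodeError, TokenSequence


def bare_plant(internode_pitch=0.0, internode_length=0.1, leaf_pitch=0.0,
               leaf_scale=1.0, base_rotation=(0.0, 0.0, 0.0), phyllo=(0.0,)):
    """Single-shoot plant with all untransformed frames unless overridden."""
    phytomers = [Phytomer(
        internode=Internode(length=internode_length, radius=0.001,
                            pitch=internode_pitch, phyllotactic_angle=a),
        petiole=Petiole(length=1e-9, radius=1e-4, pitch=0.0, curvature=0.0),
        leaves=[Leaf(scale=leaf_scale, pitch=leaf_pitch, yaw=0.0, roll=0.0),
                Leaf(scale=leaf_scale, pitch=leaf_pitch, yaw=0.0, roll=0.0)],
    ) for a in phyllo]
    return PlantArchitecture(
        base_position=(0.0, 0.0, 0.0), base_rotation=base_rotation, plant_age=0.0,
        shoots=[Shoot(0, -1, -1, 0, 1, base_pitch=0.0, base_yaw=0.0, base_roll=0.0,
                      phytomers=phytomers)])


class TestForwardKinematics:
    def test_vertical_internode_apex(self):
        geom = reconstruct_geometry(bare_plant())
        apex = geom.segments[0, 1]
        assert np.allclose(apex, [0, 0, 0.1], atol=1e-12)

    def test_untransformed_leaf_normal_is_up(self):
        geom = reconstruct_geometry(bare_plant())
        assert np.allclose(geom.leaf_normals[0], [0, 0, 1], atol=1e-12)
        hist, _ = leaf_inclination_distribution(geom)
        assert hist[0] == 1.0

    def test_phyllotaxis_rotates_petiole_azimuth(self):
        plant = bare_plant(phyllo=(0.0, 180.0))
        for ph in plant.shoots[0].phytomers:
            ph.petiole.pitch = 90.0       # horizontal petioles show azimuth
            ph.petiole.length = 0.05
        geom = reconstruct_geometry(plant)
        # petiole segments: 5 arc pieces per phytomer, after 1 internode segment each
        p0 = geom.segments[1, 1] - geom.segments[1, 0]
        p1 = geom.segments[7, 1] - geom.segments[7, 0]
        a0 = np.arctan2(p0[1], p0[0])
        a1 = np.arctan2(p1[1], p1[0])
        assert np.isclose((a1 - a0) % (2 * np.pi), np.pi, atol=1e-9)

    def test_leaf_area_scales_quadratically(self):
        g1 = reconstruct_geometry(bare_plant(leaf_scale=0.1))
        g2 = reconstruct_geometry(bare_plant(leaf_scale=0.3))
        assert np.isclose(g2.leaf_areas.sum(), 9 * g1.leaf_areas.sum())


class TestHeight:
    def test_vertical_internode_height(self):
        assert plant_height(reconstruct_geometry(bare_plant())) == pytest.approx(0.1)

    def test_horizontal_internode_contributes_nothing(self):
        h = plant_height(reconstruct_geometry(bare_plant(internode_pitch=90.0,
                                                         leaf_scale=1e-9)))
        assert h == pytest.approx(0.0, abs=1e-8)

    def test_yaw_rotation_invariance(self):
        base = bare_plant(internode_pitch=30.0)
        rotated = copy_plant(base)
        rotated.base_rotation = (0.0, 90.0, 0.0)
        assert plant_height(reconstruct_geometry(base)) == pytest.approx(
            plant_height(reconstruct_geometry(rotated)), abs=1e-12)


class TestInclination:
    def test_histogram_sums_to_one(self):
        for seed in range(3):
            geom = reconstruct_geometry(generate_plant(seed, 20))
            hist, edges = leaf_inclination_distribution(geom)
            assert hist.sum() == pytest.approx(1.0, abs=1e-9)
            assert len(hist) == 10 and edges[1] - edges[0] == 9.0

    def test_z_rotation_leaves_histogram_unchanged(self):
        plant = generate_plant(4, 25)
        rotated = copy_plant(plant)
        p, y, r = rotated.base_rotation
        rotated.base_rotation = (p, (y + 123.0) % 360, r)
        h1, _ = leaf_inclination_distribution(reconstruct_geometry(plant))
        h2, _ = leaf_inclination_distribution(reconstruct_geometry(rotated))
        assert np.allclose(h1, h2, atol=1e-9)

    def test_leafless_geometry_rejected(self):
        plant = bare_plant()
        plant.shoots[0].phytomers = []
        geom = reconstruct_geometry(plant)
        with pytest.raises(ValueError):
            leaf_inclination_distribution(geom)


class TestCountOrgans:
    def test_worked_example_counts(self, two_shoot_plant, meta, vocab):
        seq = tokenize_architecture(two_shoot_plant, meta, vocab)
        counts = count_organs(seq, vocab)
        assert (counts.n_shoots, counts.n_phytomers, counts.n_leaves) == (2, 2, 5)

    def test_counts_match_architecture_tally(self, sample_plants, vocab, meta):
        for plant in sample_plants[:8]:
            seq = tokenize_architecture(plant, meta, vocab)
            counts = count_organs(seq, vocab)
            assert counts.n_shoots == len(plant.shoots)
            assert counts.n_phytomers == sum(len(s.phytomers) for s in plant.shoots)
            assert counts.n_leaves == sum(
                len(ph.leaves) for s in plant.shoots for ph in s.phytomers)

    def test_ungrammatical_sequence_rejected(self, vocab):
        with pytest.raises(DecodeError):
            count_organs(TokenSequence((0, 1, 2)), vocab)


class TestBoundingMetadata:
    def test_leafless_plant_zero_fraction(self):
        geom = reconstruct_geometry(bare_plant(leaf_scale=1e-12))
        meta = bounding_metadata(geom, 2.0)
        assert meta.vegetation_fraction == pytest.approx(0.0, abs=1e-4)

    def test_unit_leaf_quarter_of_window(self):
        """One horizontal 1 m² lamina in a 2×2 m window covers 25 percent,
        up to one raster cell layer per edge."""
        geom = reconstruct_geometry(bare_plant(leaf_scale=1.0))
        # keep a single leaf: drop the second of the unifoliate pair
        geom.leaf_frames = geom.leaf_frames[:1]
        geom.leaf_centers = geom.leaf_centers[:1]
        geom.leaf_sides = geom.leaf_sides[:1]
        geom.leaf_normals = geom.leaf_normals[:1]
        geom.leaf_areas = geom.leaf_areas[:1]
        meta = bounding_metadata(geom, 2.0)
        assert meta.vegetation_fraction == pytest.approx(0.25, abs=2 * 4 / 256)

    def test_fraction_scales_inverse_square_with_window(self):
        geom = reconstruct_geometry(bare_plant(leaf_scale=0.5))
        f2 = bounding_metadata(geom, 2.0).vegetation_fraction
        f4 = bounding_metadata(geom, 4.0).vegetation_fraction
        assert f4 == pytest.approx(f2 / 4, rel=0.1)

    def test_height_matches_plant_height(self):
        plant = generate_plant(1, 15)
        geom = reconstruct_geometry(plant)
        meta = bounding_metadata(geom, 2.0)
        assert meta.height_m == pytest.approx(plant_height(geom))

    def test_zero_window_rejected(self):
        geom = reconstruct_geometry(bare_plant())
        with pytest.raises(ValueError):
            bounding_metadata(geom, 0.0)


class TestRigidRotationInvariance:
    def test_full_trait_invariance_under_z_rotation(self):
        plant = generate_plant(9, 30)
        rotated = copy_plant(plant)
        p, y, r = rotated.base_rotation
        rotated.base_rotation = (p, y + 77.0, r)
        g1, g2 = reconstruct_geometry(plant), reconstruct_geometry(rotated)
        assert plant_height(g1) == pytest.approx(plant_height(g2), abs=1e-9)
        assert g1.leaf_areas.sum() == pytest.approx(g2.leaf_areas.sum(), abs=1e-12)
        assert g1.n_leaves == g2.n_leaves
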
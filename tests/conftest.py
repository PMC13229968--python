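import numpy as np
import pytest

from plantarch import (
    GeneratorConfig,
    Internode,
    Leaf,
    Petiole,
    Phytomer,
    PlantArchitecture,
    PlantMetadata,
    Shoot,
    build_vocabulary,
    generate_plant,
)


@pytest.fixture(scope="session")
def vocab():
    return build_vocabulary()


def make_unifoliate_phytomer(length=0.002, pitch=0.0, phyllo=180.0):
    return Phytomer(
        internode=Internode(length=length, radius=0.0015, pitch=pitch,
                            phyllotactic_angle=phyllo),
        petiole=Petiole(length=0.0004, radius=0.0001, pitch=70.0, curvature=0.0),
        leaves=[Leaf(scale=0.02, pitch=5.0, yaw=0.0, roll=-15.0),
                Leaf(scale=0.02, pitch=-5.0, yaw=0.0, roll=-15.0)],
    )


def make_trifoliate_phytomer(phyllo=180.0):
    return Phytomer(
        internode=Internode(length=0.01, radius=0.0015, pitch=20.0,
                            phyllotactic_angle=phyllo),
        petiole=Petiole(length=0.07, radius=0.0018, pitch=50.0, curvature=-100.0,
                        leaflet_scale=0.9),
        leaves=[Leaf(scale=0.1, pitch=45.0, yaw=10.0, roll=-15.0),
                Leaf(scale=0.1, pitch=30.0, yaw=10.0, roll=-15.0),
                Leaf(scale=0.11, pitch=60.0, yaw=10.0, roll=-15.0)],
    )


@pytest.fixture
def minimal_plant():
    """Smallest valid plant: one order-0 shoot, one unifoliate phytomer."""
    return PlantArchitecture(
        base_position=(0.0, 0.0, 0.0),
        base_rotation=(5.0, 120.0, 240.0),
        plant_age=0.0,
        shoots=[Shoot(shoot_id=0, parent_shoot_id=-1, parent_node_index=-1,
                      branching_order=0, shoot_type_label=1,
                      base_pitch=40.0, base_yaw=30.0, base_roll=90.0,
                      phytomers=[make_unifoliate_phytomer()])],
    )


@pytest.fixture
def two_shoot_plant():
    """Unifoliate primary with one trifoliate lateral at node 0 —
    the layout of the worked tokenization example."""
    primary = Shoot(shoot_id=0, parent_shoot_id=-1, parent_node_index=-1,
                    branching_order=0, shoot_type_label=1,
                    base_pitch=40.0, base_yaw=30.0, base_roll=90.0,
                    phytomers=[make_unifoliate_phytomer()])
    lateral = Shoot(shoot_id=1, parent_shoot_id=0, parent_node_index=0,
                    branching_order=1, shoot_type_label=3,
                    base_pitch=50.0, base_yaw=-10.0, base_roll=90.0,
                    phytomers=[make_trifoliate_phytomer()])
    return PlantArchitecture(base_position=(0.0, 0.0, 0.0),
                             base_rotation=(2.5, 100.0, 300.0),
                             plant_age=10.0, shoots=[primary, lateral])


@pytest.fixture
def meta():
    return PlantMetadata(width_m=0.3, height_m=0.2, vegetation_fraction=0.04)


@pytest.fixture(scope="session")
def sample_plants():
    """A small seeded population spanning ages, reused across tests."""
    cfg = GeneratorConfig()
    return [generate_plant(seed, age_days=(seed * 7) % 40, config=cfg)
            for seed in range(20)]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
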
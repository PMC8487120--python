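import numpy as np
import pytest

from arcview import Centerline, PhantomSpec, VesselScene, generate_phantom


#: 64^3 spec used where speed matters more than silhouette fidelity.
SMALL_SPEC = PhantomSpec(
    arch_radius=24.0,
    tube_radius_aorta=9.0,
    tube_radius_branch=3.0,
    ascending_length=45.0,
    descending_length=52.0,
    branch_length=35.0,
    grid_shape=(64, 64, 64),
    spacing=(2.5, 2.5, 2.5),
)

#: Both branches leave the arch at the same point with different out-of-plane
#: tilts: their silhouettes overlap at every sweep angle (needs the default
#: grid resolution to hold at the sweep extremes).
COINCIDENT_SPEC = PhantomSpec(
    branch_angular_positions=(90.0, 90.0),
    branch_axis_tilt=(85.0, 55.0),
    tube_radius_branch=5.0,
)


@pytest.fixture(scope="session")
def default_scene():
    return generate_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def small_scene():
    return generate_phantom(SMALL_SPEC)


@pytest.fixture(scope="session")
def coincident_scene():
    return generate_phantom(COINCIDENT_SPEC)


def make_sphere_scene(
    r_vox: float = 12.0,
    n: int = 32,
    spacing: float = 1.0,
    origin=(0.0, 0.0, 0.0),
) -> VesselScene:
    """Sphere of radius ``r_vox`` voxels labelled 1, with a stub centerline."""
    idx = np.indices((n, n, n)).astype(float)
    c = (n - 1) / 2.0
    vol = (((idx - c) ** 2).sum(axis=0) <= r_vox**2).astype(np.int16)
    origin = np.asarray(origin, dtype=float)
    centre = c * spacing + origin
    cl = Centerline(
        np.array([centre - [5.0, 0.0, 0.0], centre + [5.0, 0.0, 0.0]]), "aorta"
    )
    return VesselScene(
        volume=vol, spacing=(spacing,) * 3, origin=origin,
        labels={"background": 0, "aorta": 1}, centerlines={"aorta": cl},
    )


@pytest.fixture()
def sphere_scene():
    return make_sphere_scene()
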
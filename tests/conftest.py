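import numpy as np
import pytest

from cartbox import ContourStack, PhantomSpec, SliceContours, generate_phantom
from cartbox.mesh import build_endocardial_mesh


def circle(radius, n=80, centre=(0.0, 0.0)):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([centre[0] + radius * np.cos(th), centre[1] + radius * np.sin(th)])


def cylinder_stack(radius=20.0, wall=8.0, n_slices=5, z_top=20.0, dz=5.0, es_shift=0.0):
    """Concentric-circle stack: a cylinder of given endo radius."""
    slices = []
    for i in range(n_slices):
        slices.append(
            SliceContours(
                z_mm=z_top - i * dz,
                endo_ed=circle(radius),
                epi_ed=circle(radius + wall),
                endo_es=circle(radius - es_shift),
                epi_es=circle(radius + wall),
            )
        )
    return ContourStack(slices=slices, pixel_spacing_mm=0.25)


@pytest.fixture(scope="session")
def cyl_stack():
    return cylinder_stack()


@pytest.fixture(scope="session")
def cyl_mesh(cyl_stack):
    return build_endocardial_mesh(cyl_stack, points_per_ring=40)


@pytest.fixture(scope="session")
def default_phantom():
    return generate_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def registration_phantom():
    """Phantom used for registration studies: mildly elliptical
    cross-section (real ventricles are not surfaces of revolution, and
    rotation about the long axis is unidentifiable on one) and a base
    extending above the equator."""
    return generate_phantom(
        PhantomSpec(
            endo_semi_axes=(25.0, 30.0, 60.0),
            base_truncation_fraction=0.3,
            contact_noise_mm=0.3,
        )
    )
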
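import numpy as np
import pytest

import fluorotrack as ft


def random_geometry(rng: np.random.Generator, image_size=(64, 64)) -> ft.ProjectionGeometry:
    """A random but valid cone-beam geometry roughly aimed at the origin."""
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    sad = rng.uniform(800.0, 1200.0)
    sdd = sad + rng.uniform(300.0, 600.0)
    src = -sad * direction
    det_c = src + sdd * direction
    # orthonormal detector axes perpendicular to the beam axis
    q, _ = np.linalg.qr(np.column_stack([direction, rng.normal(size=3), rng.normal(size=3)]))
    u, v = q[:, 1], q[:, 2]
    return ft.ProjectionGeometry(
        tuple(src), tuple(det_c), tuple(u), tuple(v), rng.uniform(0.2, 0.6), image_size
    )


@pytest.fixture(scope="session")
def stereo_geoms():
    return ft.stereo_pair(image_size=(64, 64))


@pytest.fixture(scope="session")
def default_curves():
    return ft.default_content_curves()


@pytest.fixture(scope="session")
def tiny_sequence():
    """Small rendered stereo sequence with ground truth, shared across tests."""
    vol, mask, markers = ft.make_thorax_phantom(
        tumor_center=(0.0, 0.0, 0.0),
        tumor_radii=(8.0, 8.0, 8.0),
        marker_centers=[(18.0, 10.0, 0.0)],
        voxel_spacing=(2.0, 2.0, 2.0),
        size_mm=(60.0, 60.0, 60.0),
    )
    motion = ft.MotionModel(rate_bpm=30.0, amplitude_mm=(1.0, 3.0, 1.0))
    geoms = ft.stereo_pair(image_size=(48, 48), pixel_pitch=1.0)
    seq = ft.render_sequence(vol, mask, markers, motion, geoms, n_frames=16)
    return seq, geoms, motion


@pytest.fixture(scope="session")
def e2e_sequence():
    """Stereo phantom sequence at full tracking fidelity: one complete
    breathing cycle of a 10 mm tumor on a 1 mm grid, 144 px detectors at
    0.4 mm pitch (tumor silhouette always fully inside the field of view).
    """
    vol, mask, markers = ft.make_thorax_phantom(
        tumor_center=(0.0, 0.0, 0.0),
        tumor_radii=(10.0, 10.0, 10.0),
        marker_centers=[(25.0, 15.0, 0.0)],
        voxel_spacing=(1.0, 1.0, 1.0),
        size_mm=(80.0, 80.0, 80.0),
    )
    motion = ft.MotionModel(rate_bpm=30.0, amplitude_mm=(2.0, 5.0, 2.0))
    geoms = ft.stereo_pair(image_size=(144, 144), pixel_pitch=0.4)
    seq = ft.render_sequence(vol, mask, markers, motion, geoms, n_frames=60)
    return seq, geoms, motion
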
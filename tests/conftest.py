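import numpy as np
import pytest

from gesturecap import (
    CameraParams,
    SimulationConfig,
    build_cameras,
    generate_bundle,
)


@pytest.fixture(scope="session")
def tiny_config() -> SimulationConfig:
    """One participant, one 12-s sequence: fast but structurally complete."""
    return SimulationConfig(n_participants=1, n_sequences=1, duration_s=12.0, seed=11)


@pytest.fixture(scope="session")
def tiny_bundle(tiny_config):
    return generate_bundle(tiny_config, 0, 0)


@pytest.fixture(scope="session")
def rig(tiny_config):
    cameras, scene_to_world = build_cameras(tiny_config)
    return cameras, scene_to_world


@pytest.fixture()
def simple_camera() -> CameraParams:
    """Reference camera with unit-free intrinsics and no distortion."""
    return CameraParams(
        "ref", 1000.0, 1000.0, 960.0, 540.0,
        np.zeros(5), np.eye(3), np.zeros(3),
    )


def make_camera(center, target, fx=1200.0, dist=None, camera_id="cam"):
    """Camera at ``center`` looking at ``target`` (test helper)."""
    center = np.asarray(center, dtype=float)
    target = np.asarray(target, dtype=float)
    z = target - center
    z /= np.linalg.norm(z)
    up = np.array([0.0, 1.0, 0.0])
    x = np.cross(z, up)
    x /= np.linalg.norm(x)
    y = np.cross(z, x)
    R = np.stack([x, y, z])
    return CameraParams(
        camera_id, fx, fx, 960.0, 540.0,
        np.zeros(5) if dist is None else np.asarray(dist, dtype=float),
        R, -R @ center,
    )
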
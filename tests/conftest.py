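import warnings

import numpy as np
import pytest

from rootpouch import (CleaningConfig, DistSpec, PouchImage, RootModelParams,
                       SceneParams, generate_model, render_scene)


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        yield


@pytest.fixture(scope="session")
def small_model():
    """A 12-lateral plant at moderate size, reused across tests."""
    return generate_model(RootModelParams(tap_length_cm=10.0, n_laterals=12, seed=11))


@pytest.fixture(scope="session")
def small_scene():
    return SceneParams(image_size_px=(1200, 800), pixels_per_cm=100.0, seed=21)


@pytest.fixture(scope="session")
def small_render(small_model, small_scene):
    return render_scene(small_model, small_scene)


@pytest.fixture(scope="session")
def debris_render(small_model):
    scene = SceneParams(image_size_px=(1200, 800), pixels_per_cm=100.0,
                        debris_count=30, debris_area_px=(20, 150), seed=22)
    return render_scene(small_model, scene)


@pytest.fixture
def flat_image():
    """Synthetic flat image: background 30, one bright 60x40 block at 220."""
    px = np.full((200, 300, 3), 30, np.uint8)
    px[50:110, 100:140] = 220
    return PouchImage(px, pixels_per_cm=100.0, id="flat")


@pytest.fixture
def default_cleaning():
    return CleaningConfig()


def make_mask_image(mask: np.ndarray, fg: int = 220, bg: int = 30,
                    scale: float = 100.0) -> PouchImage:
    px = np.where(mask[:, :, None], fg, bg).astype(np.uint8).repeat(3, axis=2)
    return PouchImage(px, pixels_per_cm=scale)
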
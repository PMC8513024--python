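import numpy as np
import pytest

from lesionscan import RgbImage, RunConfig, run_pipeline
from lesionscan import synthgen


@pytest.fixture(scope="session")
def small_scene():
    """A compact 3-lesion scene used by fast end-to-end tests."""
    spec = synthgen.SceneSpec(
        height=256,
        width=256,
        name="small",
        lesions=(
            synthgen.LesionSpec((80, 120), 3.0),
            synthgen.LesionSpec((170, 110), 4.0),
            synthgen.LesionSpec((180, 190), 2.5),
        ),
        seed=11,
    )
    return synthgen.generate(spec)


@pytest.fixture(scope="session")
def suite_scenes():
    """The fixed five-scene battery, generated once per session."""
    return [synthgen.generate(spec) for spec in synthgen.standard_suite(0)]


@pytest.fixture(scope="session")
def suite_results(suite_scenes):
    """Full pipeline (preprocess, 3 detectors, fusion, evaluation) per scene."""
    config = RunConfig()
    return [
        (scene, run_pipeline(scene.image, config, truth_labels=scene.truth_labels))
        for scene in suite_scenes
    ]


@pytest.fixture()
def flat_skin_image():
    """Uniform skin-tone image with exact calibration."""
    px = np.empty((64, 64, 3), dtype=np.uint8)
    px[:] = (224, 172, 105)
    return RgbImage(px, mm_per_px=0.1)
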
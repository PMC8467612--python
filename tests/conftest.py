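import hypothesis
import numpy as np
import pytest

from eyegt import pipeline, synthgen

hypothesis.settings.register_profile(
    "eyegt", deadline=None, derandomize=True, max_examples=50
)
hypothesis.settings.load_profile("eyegt")


@pytest.fixture(scope="session")
def config():
    return pipeline.PipelineConfig()


@pytest.fixture(scope="session")
def open_frame():
    """Default driver-present frame with both eyes open, plus ground truth."""
    return synthgen.render_frame(synthgen.scenario("open", seed=7))


@pytest.fixture(scope="session")
def open_result(open_frame, config):
    frame, _ = open_frame
    return pipeline.process_frame(frame, config=config, frame_id="open7")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)


def eye_window_patch(frame, pupil, offset=(0, 0), config=None):
    """Quantized window centered (plus offset) on a known pupil center."""
    from eyegt.pipeline import extract_patches, PipelineConfig

    config = config or PipelineConfig()
    ww, wh = config.search.window_size(frame.shape)
    x = pupil[0] - ww // 2 + offset[0]
    y = pupil[1] - wh // 2 + offset[1]
    return extract_patches(frame, [(x, y)], (ww, wh), config.tail_fraction)[0]
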
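import numpy as np
import pytest

from calscreen.synthetic import SceneConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_scene():
    """A fast small-field scene for smoke and pipeline tests."""
    return SceneConfig(
        frame_shape=(96, 96),
        n_frames=40,
        n_cells=4,
        radius_range=(5.0, 7.0),
        min_center_distance=24.0,
        onset_frame=10,
        seed=123,
    )


def tiny_run_config(**overrides):
    """Pipeline knobs scaled to the tiny scene (area criteria shrink with it)."""
    from calscreen.types import RunConfig

    base = dict(
        junction=150,
        stopping=900,
        elimination=60,
        n_shuffles=5,
        train_disease=2,
        train_control=2,
        cv_folds=2,
        classifier_names=("Linear SVM", "Fine Tree"),
    )
    base.update(overrides)
    return RunConfig(**base)
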
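import numpy as np
import pytest

from zfhunt.config import BehaviorSimConfig, CalciumSimConfig, PipelineConfig
from zfhunt.synthetic import simulate_calcium, simulate_session
from zfhunt.synthetic.render import RenderParams, draw_scene
from zfhunt.tracking import BackgroundModel


@pytest.fixture(scope="session")
def behavior_bundle():
    """One simulated free-swimming session with ground truth."""
    cfg = BehaviorSimConfig(seed=1, duration=60.0, hunt_rate=6.0)
    session, prey, log = simulate_session(cfg)
    return cfg, session, prey, log


@pytest.fixture(scope="session")
def calcium_bundle():
    """One simulated calcium recording at a reduced cell count."""
    cfg = CalciumSimConfig(seed=0, n_cells={"aCh-A": 20, "pCh-A": 15, "OT": 25})
    activity, trials, truth = simulate_calcium(cfg)
    return cfg, activity, trials, truth


@pytest.fixture(scope="session")
def render_params():
    return RenderParams(mode="full")


@pytest.fixture()
def flat_background():
    def make(shape=(300, 300), level=200.0):
        return BackgroundModel(background=np.full(shape, level))
    return make


@pytest.fixture()
def render_fish(render_params):
    """Render a single fish at a given pose on a flat background."""
    def make(centroid_mm=(6.0, 6.0), heading=0.0, left_eye=8.0, right_eye=-8.0,
             tail=None, shape=(300, 300), prey_mm=None):
        fish = dict(centroid=np.asarray(centroid_mm, dtype=float), heading=heading,
                    left_eye=left_eye, right_eye=right_eye)
        if tail is not None:
            fish["tail_segment_angles"] = np.asarray(tail, dtype=float)
        return draw_scene(shape, np.zeros(2), render_params, fish, prey_mm)
    return make


@pytest.fixture(scope="session")
def pipeline_config():
    return PipelineConfig()
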
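import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from avistereo import detection, scene, stereo

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rig():
    return stereo.StereoRig()


@pytest.fixture(scope="session")
def assembly():
    return scene.default_assembly()


@pytest.fixture(scope="session")
def campaign(rig, assembly):
    """The 18 scripted silhouette scenes (rendered once per session)."""
    return scene.generate_silhouette_campaign(rig, assembly, seed=3)


@pytest.fixture(scope="session")
def campaign_detections(campaign):
    """Detector output for every campaign scene, keyed (label, db_ref)."""
    out = {}
    for s in campaign:
        out[(s.label, s.db_ref)] = (
            detection.detect(s.upper_prev, s.upper_curr),
            detection.detect(s.lower_prev, s.lower_curr),
        )
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
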
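import pytest

from pairgaze.aoi_mapping import default_roi_map
from pairgaze.event_detection import DetectorParams
from pairgaze.pipeline import simulate_and_analyze
from pairgaze.study_config import build_session_plan, default_catalogue
from pairgaze.synthetic_gaze import GeneratorConfig, simulate_session


@pytest.fixture(scope="session")
def detector_params() -> DetectorParams:
    return DetectorParams()


@pytest.fixture(scope="session")
def roi_map():
    return default_roi_map()


@pytest.fixture(scope="session")
def female_catalogue():
    return default_catalogue("female")


@pytest.fixture(scope="session")
def small_session(female_catalogue):
    """One 12-trial female saline session with default generator settings."""
    cat = default_catalogue("female", pairs_per_monkey=2)
    plan = build_session_plan(cat, "M1", "SL", seed=11)
    return simulate_session(plan, GeneratorConfig(seed=5), catalogue=cat)


@pytest.fixture(scope="session")
def clean_session():
    """A blink-free, noise-free 12-trial session (exact-recovery regime)."""
    cat = default_catalogue("female", pairs_per_monkey=2)
    plan = build_session_plan(cat, "M1", "SL", seed=13)
    cfg = GeneratorConfig(seed=6, blink_rate=0.0)
    return simulate_session(plan, cfg, catalogue=cat)


@pytest.fixture(scope="session")
def sl_run():
    """9 x 120 female saline trials through the full pipeline (seeded)."""
    return simulate_and_analyze(9, "SL", seed=101)


@pytest.fixture(scope="session")
def male_run():
    """2 x 180 male saline trials through the full pipeline (seeded)."""
    return simulate_and_analyze(2, "SL", seed=303, set_label="male")


@pytest.fixture(scope="session")
def te_run():
    """9 x 120 female testosterone trials through the full pipeline (seeded)."""
    return simulate_and_analyze(9, "TE", seed=202)
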
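import pytest

from soildust import analytic_config, default_config
from soildust.diary import Diary, DiaryEvent


@pytest.fixture(scope="session")
def cfg():
    """Bundled default configuration (parsed once per session)."""
    return default_config()


@pytest.fixture(scope="session")
def point_cfg():
    """All-point analytic configuration with closed-form daily ingestion."""
    return analytic_config()


def one_hour_indoor_diary(age_group: str) -> Diary:
    """A day that is one indoor awake hour and 23 h of sleep."""
    events = [DiaryEvent(t, 60, "indoor", "sleep") for t in range(0, 720, 60)]
    events.append(DiaryEvent(720, 60, "indoor", "play"))
    events += [DiaryEvent(t, 60, "indoor", "sleep") for t in range(780, 1440, 60)]
    d = Diary(events, age_group, "spring", "weekday")
    d.validate()
    return d


@pytest.fixture
def hour_diary():
    return one_hour_indoor_diary("6m-<1y")
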
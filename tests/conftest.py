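import pandas as pd
import pytest

from straitpop.records import CAPTURE_EVENT_COLUMNS


def make_events(rows):
    """Build a schema-complete event table from partial row dicts."""
    defaults = {
        "tag_id": None,
        "event_date": "2024-06-01",
        "subregion": "Kinmen",
        "latitude": 24.45,
        "longitude": 118.3,
        "event_kind": "first_capture_tagged",
        "released": True,
        "sex": "unknown",
        "prosomal_width_cm": None,
        "gear": None,
    }
    full = [{**defaults, **r} for r in rows]
    df = pd.DataFrame(full, columns=CAPTURE_EVENT_COLUMNS)
    df["event_date"] = pd.to_datetime(df["event_date"])
    return df


@pytest.fixture
def simple_survey():
    """Tag A tagged in month 1, recaptured in month 2; tag B tagged in
    month 2."""
    return make_events(
        [
            {"tag_id": "A", "event_date": "2024-04-10"},
            {"tag_id": "A", "event_date": "2024-05-12", "event_kind": "recapture"},
            {"tag_id": "B", "event_date": "2024-05-20"},
        ]
    )
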
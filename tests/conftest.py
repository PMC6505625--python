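import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from mobsent.corpus import Corpus
from mobsent.lexicon import load_packaged_lexicon


@pytest.fixture(scope="session")
def lexicon():
    """The packaged 15-word labMT-style lexicon, neutral-band width 1."""
    return load_packaged_lexicon()


def make_corpus(rows):
    """Build a Corpus from (user_id, lat, lon, text) or full-dict rows."""
    records = []
    for i, row in enumerate(rows):
        if isinstance(row, dict):
            rec = {
                "message_id": f"m{i}",
                "time_utc": pd.Timestamp("2011-06-01 12:00:00", tz="UTC")
                + pd.Timedelta(minutes=i),
                "utc_offset_min": -300,
                **row,
            }
        else:
            uid, lat, lon, text = row
            rec = {
                "user_id": uid,
                "message_id": f"m{i}",
                "time_utc": pd.Timestamp("2011-06-01 12:00:00", tz="UTC")
                + pd.Timedelta(minutes=i),
                "utc_offset_min": -300,
                "lat": lat,
                "lon": lon,
                "text": text,
            }
        records.append(rec)
    return Corpus(pd.DataFrame.from_records(records))


@pytest.fixture
def rng():
    return np.random.default_rng(20110912)


@pytest.fixture
def cluster_corpus():
    """One user, two tight clusters ~1 km apart (15 messages each, sigma 5 m)."""
    g = np.random.default_rng(7)
    rows = []
    for cx in (0.0, 0.009):  # ~1 km in longitude at lat 40
        for _ in range(15):
            rows.append(
                (
                    "alice",
                    40.0 + g.normal(0, 5 / 111_195),
                    cx + g.normal(0, 5 / (111_195 * np.cos(np.radians(40.0)))),
                    "hello",
                )
            )
    return make_corpus(rows)
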
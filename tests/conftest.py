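import datetime as dt

import pytest
from hypothesis import settings

from sdohscan.engine import ClinicalNote
from sdohscan.query import load_default_rules

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def rules():
    return load_default_rules()


@pytest.fixture
def make_note():
    def _make(text, note_id="n1", patient_id="p1", note_type="progress note"):
        return ClinicalNote(
            note_id=note_id,
            patient_id=patient_id,
            note_type=note_type,
            date=dt.date(2018, 6, 1),
            text=text,
        )

    return _make
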
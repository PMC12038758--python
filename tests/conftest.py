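from __future__ import annotations

from datetime import date

import numpy as np
import pytest

from promdoc.corpus_prep import RawNote
from promdoc.lexicon import default_catalog
from promdoc.sections import default_section_rules


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def section_rules():
    return default_section_rules()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_raw_note(
    note_id="n1",
    visit_id="v1",
    patient_id="p1",
    service_date=date(2019, 3, 1),
    facility_id="F001",
    author_role="staff",
    text="SOAP text",
) -> RawNote:
    return RawNote(
        note_id=note_id,
        visit_id=visit_id,
        patient_id=patient_id,
        service_date=service_date,
        facility_id=facility_id,
        author_role=author_role,
        text=text,
    )
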
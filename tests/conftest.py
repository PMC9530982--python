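"""Shared fixtures: compact participant construction for tie-builder tests."""

import pytest

from confidnet import ParticipantRecord


def make_participant(
    pid,
    sex="female",
    age=70,
    district="D1",
    address="A1",
    household="H1",
    family=("山田", "やまだ"),
    given=("花子", "はなこ"),
    **kwargs,
):
    return ParticipantRecord(
        participant_id=pid,
        family_name_kanji=family[0],
        family_name_kana=family[1],
        given_name_kanji=given[0],
        given_name_kana=given[1],
        sex=sex,
        age=age,
        district_id=district,
        address_id=address,
        household_id=household,
        **kwargs,
    )


@pytest.fixture
def participant_factory():
    return make_participant
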
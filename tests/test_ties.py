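"""Two-step tie identification: household rules and 5-criterion matching."""

import pytest

from confidnet import Nomination, build_network, identify_household_ties, match_nomination
from confidnet.cohort import HouseholdMember
from confidnet.ties import AMBIGUOUS, MATCHED, NO_CANDIDATE

from conftest import make_participant


def spouse_pair(satisfaction=3, reports_confidant=True, wife_age=68, husband_age=72):
    """Opposite-sex co-residing couple; the husband is the respondent."""
    husband = make_participant(
        "h",
        sex="male",
        age=husband_age,
        household="H9",
        address="A9",
        given=("博", "ひろし"),
        marital_satisfaction=satisfaction,
        reports_any_confidant=reports_confidant,
        household_members=[
            HouseholdMember(
                family_name_kanji="山田",
                family_name_kana="やまだ",
                given_name_kanji="花子",
                given_name_kana="はなこ",
                sex="female",
                age=wife_age,
            )
        ],
    )
    wife = make_participant(
        "w", sex="female", age=wife_age, household="H9", address="A9"
    )
    return husband, wife


class TestHouseholdTies:
    def test_coresident_participant_becomes_confidant(self):
        husband, wife = spouse_pair()
        assert identify_household_ties(husband, [husband, wife]) == {("h", "w")}

    def test_same_sex_coresident_tied_regardless_of_satisfaction(self):
        resp = make_participant(
            "a",
            sex="male",
            age=70,
            household="H1",
            given=("博", "ひろし"),
            marital_satisfaction=9,
            reports_any_confidant=False,
            household_members=[
                HouseholdMember(
                    family_name_kanji="山田",
                    family_name_kana="やまだ",
                    given_name_kanji="茂",
                    given_name_kana="しげる",
                    sex="male",
                    age=68,
                )
            ],
        )
        brother = make_participant(
            "b", sex="male", age=68, household="H1", given=("茂", "しげる")
        )
        assert identify_household_ties(resp, [resp, brother]) == {("a", "b")}

    @pytest.mark.parametrize(
        "satisfaction, reports, age_gap, tie_expected",
        [
            (9, False, 10, False),  # poor + no confidants + likely spouse: suppressed
            (9, False, 20, True),  # age gap >= 15: exception does not apply
            (9, True, 10, True),  # reports confidants: no suppression
            (3, False, 10, True),  # satisfied: no suppression
            (7, False, 14, False),  # threshold is >6; 14 < 15 suppressed
            (6, False, 10, True),  # exactly 6 is not "poor"
        ],
    )
    def test_likely_spouse_suppression(self, satisfaction, reports, age_gap, tie_expected):
        husband, wife = spouse_pair(
            satisfaction=satisfaction,
            reports_confidant=reports,
            husband_age=65 + age_gap,
            wife_age=65,
        )
        ties = identify_household_ties(husband, [husband, wife])
        assert (("h", "w") in ties) == tie_expected

    def test_nonparticipant_member_yields_no_tie(self):
        husband, _ = spouse_pair()
        assert identify_household_ties(husband, [husband]) == set()


class TestMatchNomination:
    def base_roster(self):
        nominator = make_participant(
            "n", sex="female", age=70, district="D1", address="A1",
            family=("佐藤", "さとう"), given=("幸子", "さちこ"),
        )
        target = make_participant(
            "t", sex="female", age=72, district="D1", address="A2", household="H2",
        )
        return nominator, target

    def nomination(self):
        return Nomination(
            nominator_id="n",
            family_name_kanji="山田",
            given_name_kanji="花子",
            family_name_kana="やまだ",
            given_name_kana="はなこ",
        )

    def test_unique_candidate_matches(self):
        nominator, target = self.base_roster()
        matched, outcome = match_nomination(self.nomination(), nominator, [nominator, target])
        assert matched == "t" and outcome.status == MATCHED

    def test_kana_only_spelling_suffices(self):
        nominator, target = self.base_roster()
        nom = Nomination(nominator_id="n", family_name_kana="やまだ", given_name_kana="はなこ")
        matched, _ = match_nomination(nom, nominator, [nominator, target])
        assert matched == "t"

    @pytest.mark.parametrize(
        "mutation",
        ["name", "sex", "age", "district", "same_address"],
    )
    def test_each_criterion_excludes(self, mutation):
        nominator, target = self.base_roster()
        if mutation == "name":
            target.given_name_kanji, target.given_name_kana = "良子", "よしこ"
        elif mutation == "sex":
            target.sex = "male"
        elif mutation == "age":
            target.age = 74  # gap 4 > 3
        elif mutation == "district":
            target.district_id = "D2"
        elif mutation == "same_address":
            target.address_id = nominator.address_id
        matched, outcome = match_nomination(self.nomination(), nominator, [nominator, target])
        assert matched is None and outcome.status == NO_CANDIDATE

    def test_age_gap_boundary_three_years_matches(self):
        nominator, target = self.base_roster()
        target.age = 73  # gap exactly 3: "no more than 3 years"
        matched, _ = match_nomination(self.nomination(), nominator, [nominator, target])
        assert matched == "t"

    def test_two_candidates_are_ambiguous(self):
        nominator, target = self.base_roster()
        twin = make_participant(
            "t2", sex="female", age=71, district="D1", address="A3", household="H3"
        )
        matched, outcome = match_nomination(
            self.nomination(), nominator, [nominator, target, twin]
        )
        assert matched is None
        assert outcome.status == AMBIGUOUS and outcome.n_candidates == 2


class TestBuildNetwork:
    def test_empty_inputs_give_empty_network(self):
        a = make_participant("a", household="H1", address="A1")
        b = make_participant("b", household="H2", address="A2")
        network, report = build_network([a, b])
        assert network.n_edges == 0 and not report.outcomes

    def test_household_pair_plus_nomination(self):
        # 1 household pair (2 reciprocal ties) + 1 unambiguous nomination (1 one-way)
        husband, wife = spouse_pair()
        wife.household_members = [
            HouseholdMember(
                family_name_kanji="山田", family_name_kana="やまだ",
                given_name_kanji="博", given_name_kana="ひろし",
                sex="male", age=husband.age,
            )
        ]
        friend = make_participant(
            "f", sex="female", age=69, district="D1", address="A5", household="H5",
            family=("鈴木", "すずき"), given=("和子", "かずこ"),
        )
        wife.community_nominations = [
            Nomination(
                nominator_id="w", family_name_kanji="鈴木", given_name_kanji="和子",
                family_name_kana="すずき", given_name_kana="かずこ",
            )
        ]
        network, report = build_network([husband, wife, friend])
        assert network.edges == {("h", "w"), ("w", "h"), ("w", "f")}
        assert network.tie_provenance[("w", "f")] == "community"
        assert network.tie_provenance[("h", "w")] == "household"
        assert report.n_matched == 1

    def test_duplicate_participant_id_is_hard_error(self):
        a = make_participant("a")
        with pytest.raises(ValueError, match="duplicate"):
            build_network([a, make_participant("a")])

    def test_determinism_and_nomination_monotonicity(self):
        husband, wife = spouse_pair()
        friend = make_participant(
            "f", sex="female", age=69, district="D1", address="A5", household="H5",
            family=("鈴木", "すずき"), given=("和子", "かずこ"),
        )
        wife.community_nominations = [
            Nomination(
                nominator_id="w", family_name_kanji="鈴木", given_name_kanji="和子",
                family_name_kana="すずき", given_name_kana="かずこ",
            )
        ]
        roster = [husband, wife, friend]
        net1, _ = build_network(roster)
        net2, _ = build_network(roster)
        assert net1.edges == net2.edges
        wife.community_nominations = []  # removing a nomination never adds a tie
        net3, _ = build_network(roster)
        assert net3.edges <= net1.edges
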
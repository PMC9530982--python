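"""Two-step confidant tie identification from survey records.

Step 1 (household): every co-residing participant is a confidant of the
respondent, except that a respondent reporting poor marital satisfaction
(>6 on a 10-point dissatisfaction Likert by default) together with absence
of confidants does not get ties to opposite-sex co-residents within 15 years
of age (the likely-spouse exception).

Step 2 (community): each name-only nomination is matched against the roster
under five criteria — (1) exact name equality in the kanji fields or the
kana fields, (2) same sex as the nominator, (3) at most 3 years of age
difference from the nominator, (4) same residential district but a different
address, and (5) uniqueness: exactly one roster member may satisfy (1)-(4).

Matching is exact-string after Unicode NFC normalization and whitespace
trimming; there is no fuzzy matching.  Every nomination receives exactly one
audit outcome (matched / no_candidate / ambiguous) in a MatchReport.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

from .cohort import (
    HouseholdMember,
    Nomination,
    ParticipantRecord,
    code_covariates,
    normalize_name,
    score_gds,
)
from .network import (
    PROVENANCE_COMMUNITY,
    PROVENANCE_HOUSEHOLD,
    DirectedNetwork,
    Edge,
)

MATCHED = "matched"
NO_CANDIDATE = "no_candidate"
AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class TieBuilderConfig:
    """Tunable rules of the identification procedure.

    poor_satisfaction_threshold
        Marital satisfaction strictly above this value counts as "poor";
        the scale is oriented so higher = more dissatisfied.
    spouse_age_gap_years
        The likely-spouse exception suppresses ties to opposite-sex
        co-residents with an age gap strictly below this many years.
    nomination_age_tolerance_years
        Criterion (3): candidate age within this many years of the nominator.
    household_age_tolerance_years
        Tolerance when resolving a listed household member to a roster
        participant (age self-reports may disagree by a year).
    """

    poor_satisfaction_threshold: int = 6
    spouse_age_gap_years: int = 15
    nomination_age_tolerance_years: int = 3
    household_age_tolerance_years: int = 1


DEFAULT_TIE_CONFIG = TieBuilderConfig()


@dataclass(frozen=True)
class MatchOutcome:
    """Audit record for one nomination."""

    nominator_id: str
    status: str  # matched / no_candidate / ambiguous
    matched_id: Optional[str] = None
    n_candidates: int = 0
    nominated_name: str = ""

    def as_dict(self) -> dict:
        return {
            "nominator_id": self.nominator_id,
            "status": self.status,
            "matched_id": self.matched_id,
            "n_candidates": self.n_candidates,
            "nominated_name": self.nominated_name,
        }


@dataclass
class MatchReport:
    """Per-nomination outcomes plus household-resolution misses."""

    outcomes: List[MatchOutcome] = field(default_factory=list)
    unresolved_household_members: List[Tuple[str, str]] = field(default_factory=list)

    @property
    def n_matched(self) -> int:
        return sum(1 for o in self.outcomes if o.status == MATCHED)

    @property
    def n_ambiguous(self) -> int:
        return sum(1 for o in self.outcomes if o.status == AMBIGUOUS)

    @property
    def n_no_candidate(self) -> int:
        return sum(1 for o in self.outcomes if o.status == NO_CANDIDATE)


def _names_equal(
    a_family_kanji: str,
    a_given_kanji: str,
    a_family_kana: str,
    a_given_kana: str,
    b: ParticipantRecord,
) -> bool:
    """Criterion (1): full-name equality in the kanji fields OR the kana fields."""
    fk, gk = normalize_name(a_family_kanji), normalize_name(a_given_kanji)
    fh, gh = normalize_name(a_family_kana), normalize_name(a_given_kana)
    kanji_ok = bool(fk and gk) and fk == normalize_name(b.family_name_kanji) and gk == normalize_name(
        b.given_name_kanji
    )
    kana_ok = bool(fh and gh) and fh == normalize_name(b.family_name_kana) and gh == normalize_name(
        b.given_name_kana
    )
    return kanji_ok or kana_ok


def _poor_satisfaction_no_confidant(
    record: ParticipantRecord, config: TieBuilderConfig
) -> bool:
    return (
        record.marital_satisfaction is not None
        and record.marital_satisfaction > config.poor_satisfaction_threshold
        and record.reports_any_confidant is False
    )


def _resolve_household_member(
    member: HouseholdMember,
    record: ParticipantRecord,
    cohabitants: Sequence[ParticipantRecord],
    config: TieBuilderConfig,
) -> Optional[ParticipantRecord]:
    """Resolve a listed household member to a co-registered roster participant.

    Requires the shared household_id (implicit in ``cohabitants``), exact name
    match, sex agreement, and age agreement within the configured tolerance.
    """
    for other in cohabitants:
        if other.participant_id == record.participant_id:
            continue
        if not _names_equal(
            member.family_name_kanji,
            member.given_name_kanji,
            member.family_name_kana,
            member.given_name_kana,
            other,
        ):
            continue
        if member.sex is not None and member.sex != other.sex:
            continue
        if (
            member.age is not None
            and abs(member.age - other.age) > config.household_age_tolerance_years
        ):
            continue
        return other
    return None


def identify_household_ties(
    record: ParticipantRecord,
    roster: Sequence[ParticipantRecord],
    config: TieBuilderConfig = DEFAULT_TIE_CONFIG,
    report: Optional[MatchReport] = None,
) -> Set[Edge]:
    """Household-based confidant ties of one respondent.

    Emits ``record -> member`` for each household member resolvable to a
    co-residing roster participant, applying the likely-spouse suppression
    when the respondent reports poor marital satisfaction and no confidants.
    Members who are not study participants yield no tie.
    """
    cohabitants = [
        r
        for r in roster
        if r.household_id == record.household_id and r.household_id != ""
    ]
    suppress_spouse_like = _poor_satisfaction_no_confidant(record, config)
    ties: Set[Edge] = set()
    for member in record.household_members:
        other = _resolve_household_member(member, record, cohabitants, config)
        if other is None:
            if report is not None:
                name = normalize_name(member.family_name_kanji + member.given_name_kanji) or (
                    normalize_name(member.family_name_kana + member.given_name_kana)
                )
                report.unresolved_household_members.append((record.participant_id, name))
            continue
        if (
            suppress_spouse_like
            and other.sex != record.sex
            and abs(record.age - other.age) < config.spouse_age_gap_years
        ):
            continue
        ties.add((record.participant_id, other.participant_id))
    return ties


def match_nomination(
    nomination: Nomination,
    nominator: ParticipantRecord,
    roster: Sequence[ParticipantRecord],
    config: TieBuilderConfig = DEFAULT_TIE_CONFIG,
) -> Tuple[Optional[str], MatchOutcome]:
    """Match one community nomination against the roster under criteria (1)-(5).

    Criteria (2)-(4) compare the candidate against the *nominator* (same sex,
    age within 3 years, same district, different address) because the
    nomination itself carries only a name.  Returns the matched participant id
    iff exactly one roster member satisfies (1)-(4); two or more candidates
    produce an ``ambiguous`` outcome and no match (criterion 5).
    """
    name_repr = (
        normalize_name(nomination.family_name_kanji + nomination.given_name_kanji)
        or normalize_name(nomination.family_name_kana + nomination.given_name_kana)
    )
    candidates = []
    for other in roster:
        if other.participant_id == nominator.participant_id:
            continue
        if not _names_equal(
            nomination.family_name_kanji,
            nomination.given_name_kanji,
            nomination.family_name_kana,
            nomination.given_name_kana,
            other,
        ):
            continue  # criterion (1)
        if other.sex != nominator.sex:
            continue  # criterion (2)
        if abs(other.age - nominator.age) > config.nomination_age_tolerance_years:
            continue  # criterion (3)
        if other.district_id != nominator.district_id:
            continue  # criterion (4a)
        if other.address_id == nominator.address_id:
            continue  # criterion (4b): not the same residential address
        candidates.append(other)
    if len(candidates) == 1:
        matched = candidates[0].participant_id
        return matched, MatchOutcome(
            nominator_id=nominator.participant_id,
            status=MATCHED,
            matched_id=matched,
            n_candidates=1,
            nominated_name=name_repr,
        )
    status = NO_CANDIDATE if not candidates else AMBIGUOUS
    return None, MatchOutcome(
        nominator_id=nominator.participant_id,
        status=status,
        matched_id=None,
        n_candidates=len(candidates),
        nominated_name=name_repr,
    )


def build_network(
    records: Sequence[ParticipantRecord],
    config: TieBuilderConfig = DEFAULT_TIE_CONFIG,
    attach_attributes: bool = True,
) -> Tuple[DirectedNetwork, MatchReport]:
    """Build the directed confidant network over the analysis set.

    The network is the union of household ties and uniquely matched community
    nominations; tie provenance is recorded per edge (a tie identified both
    ways keeps its household label).  Deterministic given its inputs.
    """
    ids = [r.participant_id for r in records]
    if len(set(ids)) != len(ids):
        seen: Set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
        raise ValueError(f"duplicate participant_id {dup!r} in roster")

    report = MatchReport()
    network = DirectedNetwork(nodes=list(ids))

    for record in records:
        for edge in identify_household_ties(record, records, config, report):
            network.add_edge(*edge, provenance=PROVENANCE_HOUSEHOLD)

    for record in records:
        for nomination in record.community_nominations:
            matched, outcome = match_nomination(nomination, record, records, config)
            report.outcomes.append(outcome)
            if matched is not None:
                edge = (record.participant_id, matched)
                if edge not in network.edges:
                    network.add_edge(*edge, provenance=PROVENANCE_COMMUNITY)

    if attach_attributes:
        for record in records:
            scores = score_gds(record.gds_items)
            cov = code_covariates(record, scores)
            network.node_attributes[record.participant_id] = cov.as_dict()

    return network, report
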
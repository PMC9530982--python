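"""Participant domain types, GDS-15 scoring with subscales, and covariate coding.

The Geriatric Depression Scale (GDS-15) is a 15-item yes/no screening
instrument for late-life depression; each item contributes one point when
answered in the symptomatic direction, so totals run 0–15 with higher scores
indicating more depressive symptoms.  Five of the items are positively worded
("Are you basically satisfied with your life?", "full of energy", ...) and
score on "no"; the remaining ten score on "yes".

Two validated subscales are carved out of the 15 items:

* the 3-item **apathy** subscale ("dropped many of your activities and
  interests", "prefer to stay at home", "full of energy"), range 0–3, and
* the 5-item **suicidal-ideation** subscale ("life is empty", "happy most of
  the time", "wonderful to be alive", "pretty worthless", "situation is
  hopeless"), range 0–5.

The two item sets are disjoint, so apathy + suicidal_ideation <= gds_total.

Covariate coding follows the study's reference categories: female vs male,
age >= 75 vs < 75, living with family (household of 2+) vs alone, disability
(TMIG-IC < 13) vs none, and education dummies against the "<= 9 years" band.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

MALE = "male"
FEMALE = "female"
SEXES = (MALE, FEMALE)

YES = "yes"
NO = "no"

# Education bands; "<=9" pools "<6" and "6-9" as the model's reference category.
EDU_LT6 = "<6"
EDU_6_9 = "6-9"
EDU_10_12 = "10-12"
EDU_13_PLUS = "13+"
EDU_OTHER = "other"
EDUCATION_BANDS = (EDU_LT6, EDU_6_9, EDU_10_12, EDU_13_PLUS, EDU_OTHER)

#: Standard GDS-15 item texts, in instrument order (0-based indices used below).
GDS15_ITEM_TEXTS = (
    "Are you basically satisfied with your life?",
    "Have you dropped many of your activities and interests?",
    "Do you feel that your life is empty?",
    "Do you often get bored?",
    "Are you in good spirits most of the time?",
    "Are you afraid that something bad is going to happen to you?",
    "Do you feel happy most of the time?",
    "Do you often feel helpless?",
    "Do you prefer to stay at home, rather than going out and doing new things?",
    "Do you feel you have more problems with memory than most?",
    "Do you think it is wonderful to be alive now?",
    "Do you feel pretty worthless the way you are now?",
    "Do you feel full of energy?",
    "Do you feel that your situation is hopeless?",
    "Do you think that most people are better off than you are?",
)


@dataclass(frozen=True)
class GdsKey:
    """Item map for GDS-15 scoring: reverse-keyed items and subscale item sets.

    Kept as data (not hard-coded logic) so an alternative keying can be
    swapped in; the default is the standard published GDS-15 keying.
    """

    reverse_keyed: frozenset = frozenset({0, 4, 6, 10, 12})
    apathy_items: Tuple[int, ...] = (1, 8, 12)
    suicidal_items: Tuple[int, ...] = (2, 6, 10, 11, 13)

    def __post_init__(self) -> None:
        if set(self.apathy_items) & set(self.suicidal_items):
            raise ValueError("apathy and suicidal-ideation item sets must be disjoint")
        for idx in (*self.apathy_items, *self.suicidal_items, *self.reverse_keyed):
            if not 0 <= idx < 15:
                raise ValueError(f"item index {idx} out of range 0..14")


STANDARD_GDS_KEY = GdsKey()


@dataclass(frozen=True)
class DepressionScores:
    """GDS-15 total with apathy and suicidal-ideation subscale scores."""

    gds_total: int
    apathy: int
    suicidal_ideation: int

    def __post_init__(self) -> None:
        if not 0 <= self.gds_total <= 15:
            raise ValueError("gds_total out of range 0-15")
        if not 0 <= self.apathy <= 3:
            raise ValueError("apathy out of range 0-3")
        if not 0 <= self.suicidal_ideation <= 5:
            raise ValueError("suicidal_ideation out of range 0-5")
        if self.apathy + self.suicidal_ideation > self.gds_total:
            raise ValueError("subscales exceed total (item sets are disjoint)")


@dataclass(frozen=True)
class Nomination:
    """A name-only community confidant nomination made by a participant."""

    nominator_id: str
    family_name_kanji: str = ""
    given_name_kanji: str = ""
    family_name_kana: str = ""
    given_name_kana: str = ""

    def __post_init__(self) -> None:
        if not any(
            (
                self.family_name_kanji,
                self.given_name_kanji,
                self.family_name_kana,
                self.given_name_kana,
            )
        ):
            raise ValueError("nomination must carry at least one name field")


@dataclass(frozen=True)
class HouseholdMember:
    """A co-residing household member as listed by the respondent."""

    family_name_kanji: str = ""
    given_name_kanji: str = ""
    family_name_kana: str = ""
    given_name_kana: str = ""
    sex: Optional[str] = None
    age: Optional[int] = None
    relationship: Optional[str] = None


@dataclass
class ParticipantRecord:
    """One survey respondent: identity, demographics, household, nominations, items."""

    participant_id: str
    family_name_kanji: str = ""
    given_name_kanji: str = ""
    family_name_kana: str = ""
    given_name_kana: str = ""
    sex: str = MALE
    age: int = 65
    district_id: str = ""
    address_id: str = ""
    household_id: str = ""
    marital_satisfaction: Optional[int] = None  # 1-10 Likert, higher = more dissatisfied
    reports_any_confidant: Optional[bool] = None
    household_members: List[HouseholdMember] = field(default_factory=list)
    community_nominations: List[Nomination] = field(default_factory=list)
    gds_items: Optional[Sequence[Optional[str]]] = None  # 15 x yes/no
    smc_items: Optional[Sequence[Optional[int]]] = None  # 4 frequency items, 1-7
    smc_severe_problem: Optional[bool] = None
    tmig_items: Optional[Sequence[Optional[int]]] = None  # 13 x {0,1}
    education_years_band: str = EDU_OTHER

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.age < 65:
            raise ValueError("participants are community-dwelling adults aged >= 65")
        if self.education_years_band not in EDUCATION_BANDS:
            raise ValueError(f"unknown education band {self.education_years_band!r}")
        if self.gds_items is not None and len(self.gds_items) != 15:
            raise ValueError("gds_items must have length 15 when present")
        if self.tmig_items is not None and len(self.tmig_items) != 13:
            raise ValueError("tmig_items must have length 13 when present")


@dataclass(frozen=True)
class CovariateVector:
    """Node-level covariates coded against the model's reference categories.

    ``None`` marks a missing value; participants with missing model covariates
    are excluded listwise at fit time, never silently zero-filled.
    """

    female: int
    age_ge75: int
    lives_with_family: int
    disability: Optional[int]
    edu_10_12: Optional[int]
    edu_13plus: Optional[int]
    smc_score: Optional[int]
    gds_total: Optional[int]
    apathy: Optional[int]
    suicidal_ideation: Optional[int]

    def __post_init__(self) -> None:
        if self.edu_10_12 and self.edu_13plus:
            raise ValueError("education dummies cannot both be 1")
        if self.smc_score is not None and not 4 <= self.smc_score <= 28:
            raise ValueError("smc_score must lie in [4, 28]")

    def as_dict(self) -> dict:
        return {
            "female": self.female,
            "age_ge75": self.age_ge75,
            "lives_with_family": self.lives_with_family,
            "disability": self.disability,
            "edu_10_12": self.edu_10_12,
            "edu_13plus": self.edu_13plus,
            "smc_score": self.smc_score,
            "gds_total": self.gds_total,
            "apathy": self.apathy,
            "suicidal_ideation": self.suicidal_ideation,
        }


def normalize_name(name: str) -> str:
    """Unicode NFC normalization plus whitespace trimming (exact-match linkage)."""
    return unicodedata.normalize("NFC", name or "").strip()


def score_gds(
    gds_items: Optional[Sequence[Optional[str]]],
    key: GdsKey = STANDARD_GDS_KEY,
) -> Optional[DepressionScores]:
    """Score 15 yes/no GDS items into total, apathy and suicidal-ideation scores.

    An item contributes 1 when answered in the symptomatic direction:
    "yes" for the ten negatively worded items, "no" for the five reverse-keyed
    positively worded items.  Any missing or unanswerable item yields ``None``
    (the participant is excluded from the analysis set), never a zero-fill.
    """
    if gds_items is None or len(gds_items) != 15:
        return None
    points = []
    for idx, answer in enumerate(gds_items):
        if answer is None:
            return None
        answer = str(answer).strip().lower()
        if answer not in (YES, NO):
            return None
        symptomatic = (answer == NO) if idx in key.reverse_keyed else (answer == YES)
        points.append(1 if symptomatic else 0)
    return DepressionScores(
        gds_total=sum(points),
        apathy=sum(points[i] for i in key.apathy_items),
        suicidal_ideation=sum(points[i] for i in key.suicidal_items),
    )


def score_smc(smc_items: Optional[Sequence[Optional[int]]]) -> Optional[int]:
    """Sum the four SMC frequency items (each 1-7) into a 4-28 complaint score.

    Higher scores indicate more subjective memory complaints.  The separate
    severe-problem indicator is metadata and does not enter the score.
    """
    if smc_items is None or len(smc_items) != 4:
        return None
    total = 0
    for item in smc_items:
        if item is None:
            return None
        item = int(item)
        if not 1 <= item <= 7:
            raise ValueError(f"SMC item response {item} outside 1-7")
        total += item
    return total


def code_disability(tmig_items: Optional[Sequence[Optional[int]]]) -> Optional[int]:
    """Disability indicator from the 13-item TMIG Index of Competence.

    Any score below the full 13 points codes as disability (1); the full
    score codes 0.  Missing items yield a missing code.
    """
    if tmig_items is None or len(tmig_items) != 13:
        return None
    total = 0
    for item in tmig_items:
        if item is None:
            return None
        item = int(item)
        if item not in (0, 1):
            raise ValueError(f"TMIG-IC item response {item} not in {{0,1}}")
        total += item
    return 1 if total < 13 else 0


def code_covariates(
    record: ParticipantRecord,
    scores: Optional[DepressionScores] = None,
) -> CovariateVector:
    """Code a participant's covariates against the model reference categories.

    * female = 1 vs male reference;
    * age_ge75 = 1 iff age >= 75 (reference "<75 years");
    * lives_with_family = 1 iff the household has 2+ members (self included);
    * disability from TMIG-IC (<13 = 1), missing when items are missing;
    * education dummies vs the pooled "<= 9 years" reference; the
      "other/unknown" band yields missing dummies (listwise handled at fit);
    * SMC score 4-28 (missing when items are missing).
    """
    if scores is None:
        scores = score_gds(record.gds_items)
    household_size = 1 + len(record.household_members)
    band = record.education_years_band
    if band == EDU_OTHER:
        edu_10_12: Optional[int] = None
        edu_13plus: Optional[int] = None
    else:
        edu_10_12 = 1 if band == EDU_10_12 else 0
        edu_13plus = 1 if band == EDU_13_PLUS else 0
    return CovariateVector(
        female=1 if record.sex == FEMALE else 0,
        age_ge75=1 if record.age >= 75 else 0,
        lives_with_family=1 if household_size >= 2 else 0,
        disability=code_disability(record.tmig_items),
        edu_10_12=edu_10_12,
        edu_13plus=edu_13plus,
        smc_score=score_smc(record.smc_items),
        gds_total=scores.gds_total if scores else None,
        apathy=scores.apathy if scores else None,
        suicidal_ideation=scores.suicidal_ideation if scores else None,
    )


def similarity(score_i: Optional[int], score_j: Optional[int]) -> int:
    """Absolute score difference — the dyadic (dis)similarity used for homophily.

    Zero iff the two scores are equal; symmetric in its arguments.
    """
    if score_i is None or score_j is None:
        raise ValueError("similarity requires both scores present")
    return abs(int(score_i) - int(score_j))
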
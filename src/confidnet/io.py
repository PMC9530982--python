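"""Survey table I/O: the CSV dialect consumed and produced by the pipeline.

Three UTF-8 delimited tables describe a survey:

``participants.csv`` — one row per respondent
    participant_id; family_name_kanji, given_name_kanji, family_name_kana,
    given_name_kana; sex (male/female); age; district_id; address_id;
    household_id; marital_satisfaction (1-10, higher = more dissatisfied,
    blank if absent); reports_any_confidant (true/false/blank);
    education_years_band (<6, 6-9, 10-12, 13+, other); gds_item_01..15
    (yes/no); smc_item_1..4 (1-7); smc_severe_problem (true/false);
    tmig_item_01..13 (0/1).

``household_members.csv`` — one row per listed co-resident, keyed by
    participant_id; name fields as above; sex; age; relationship.

``nominations.csv`` — one row per community confidant nomination, keyed by
    nominator_id; name fields only.

Edge lists are TSV (source, target, provenance); match reports are JSON
lines; fit and descriptive reports are CSV/JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import pandas as pd

from .cohort import (
    HouseholdMember,
    Nomination,
    ParticipantRecord,
    code_covariates,
    score_gds,
)
from .network import DirectedNetwork, from_edge_list
from .ties import MatchReport

PathLike = Union[str, Path]

_NAME_COLS = (
    "family_name_kanji",
    "given_name_kanji",
    "family_name_kana",
    "given_name_kana",
)
GDS_COLS = [f"gds_item_{k:02d}" for k in range(1, 16)]
SMC_COLS = [f"smc_item_{k}" for k in range(1, 5)]
TMIG_COLS = [f"tmig_item_{k:02d}" for k in range(1, 14)]


def _opt(value) -> Optional[str]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    return value


def records_to_tables(
    records: Sequence[ParticipantRecord],
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """(participants, household_members, nominations) DataFrames."""
    part_rows, member_rows, nomination_rows = [], [], []
    for r in records:
        row = {
            "participant_id": r.participant_id,
            **{c: getattr(r, c) for c in _NAME_COLS},
            "sex": r.sex,
            "age": r.age,
            "district_id": r.district_id,
            "address_id": r.address_id,
            "household_id": r.household_id,
            "marital_satisfaction": r.marital_satisfaction,
            "reports_any_confidant": r.reports_any_confidant,
            "education_years_band": r.education_years_band,
            "smc_severe_problem": r.smc_severe_problem,
        }
        for k, col in enumerate(GDS_COLS):
            row[col] = r.gds_items[k] if r.gds_items is not None else None
        for k, col in enumerate(SMC_COLS):
            row[col] = r.smc_items[k] if r.smc_items is not None else None
        for k, col in enumerate(TMIG_COLS):
            row[col] = r.tmig_items[k] if r.tmig_items is not None else None
        part_rows.append(row)
        for m in r.household_members:
            member_rows.append(
                {
                    "participant_id": r.participant_id,
                    "family_name_kanji": m.family_name_kanji,
                    "given_name_kanji": m.given_name_kanji,
                    "family_name_kana": m.family_name_kana,
                    "given_name_kana": m.given_name_kana,
                    "sex": m.sex,
                    "age": m.age,
                    "relationship": m.relationship,
                }
            )
        for nom in r.community_nominations:
            nomination_rows.append(
                {
                    "nominator_id": nom.nominator_id,
                    "family_name_kanji": nom.family_name_kanji,
                    "given_name_kanji": nom.given_name_kanji,
                    "family_name_kana": nom.family_name_kana,
                    "given_name_kana": nom.given_name_kana,
                }
            )
    participants = pd.DataFrame(part_rows)
    members = pd.DataFrame(
        member_rows,
        columns=["participant_id", *_NAME_COLS, "sex", "age", "relationship"],
    )
    nominations = pd.DataFrame(nomination_rows, columns=["nominator_id", *_NAME_COLS])
    return participants, members, nominations


def tables_to_records(
    participants: pd.DataFrame,
    members: Optional[pd.DataFrame] = None,
    nominations: Optional[pd.DataFrame] = None,
) -> List[ParticipantRecord]:
    """Rebuild participant records from the three survey tables."""
    members_by_id: Dict[str, List[HouseholdMember]] = {}
    if members is not None and len(members):
        for _, m in members.iterrows():
            members_by_id.setdefault(str(m["participant_id"]), []).append(
                HouseholdMember(
                    family_name_kanji=str(_opt(m.get("family_name_kanji")) or ""),
                    given_name_kanji=str(_opt(m.get("given_name_kanji")) or ""),
                    family_name_kana=str(_opt(m.get("family_name_kana")) or ""),
                    given_name_kana=str(_opt(m.get("given_name_kana")) or ""),
                    sex=_opt(m.get("sex")),
                    age=None if _opt(m.get("age")) is None else int(m["age"]),
                    relationship=_opt(m.get("relationship")),
                )
            )
    noms_by_id: Dict[str, List[Nomination]] = {}
    if nominations is not None and len(nominations):
        for _, nm in nominations.iterrows():
            nominator = str(nm["nominator_id"])
            noms_by_id.setdefault(nominator, []).append(
                Nomination(
                    nominator_id=nominator,
                    family_name_kanji=str(_opt(nm.get("family_name_kanji")) or ""),
                    given_name_kanji=str(_opt(nm.get("given_name_kanji")) or ""),
                    family_name_kana=str(_opt(nm.get("family_name_kana")) or ""),
                    given_name_kana=str(_opt(nm.get("given_name_kana")) or ""),
                )
            )
    records = []
    for _, row in participants.iterrows():
        pid = str(row["participant_id"])
        gds = [_opt(row.get(c)) for c in GDS_COLS]
        smc = [
            None if _opt(row.get(c)) is None else int(float(row[c])) for c in SMC_COLS
        ]
        tmig = [
            None if _opt(row.get(c)) is None else int(float(row[c])) for c in TMIG_COLS
        ]
        satisfaction = _opt(row.get("marital_satisfaction"))
        reports = _opt(row.get("reports_any_confidant"))
        if isinstance(reports, str):
            reports = reports.strip().lower() in ("true", "1", "yes")
        severe = _opt(row.get("smc_severe_problem"))
        if isinstance(severe, str):
            severe = severe.strip().lower() in ("true", "1", "yes")
        records.append(
            ParticipantRecord(
                participant_id=pid,
                family_name_kanji=str(_opt(row.get("family_name_kanji")) or ""),
                given_name_kanji=str(_opt(row.get("given_name_kanji")) or ""),
                family_name_kana=str(_opt(row.get("family_name_kana")) or ""),
                given_name_kana=str(_opt(row.get("given_name_kana")) or ""),
                sex=str(row["sex"]),
                age=int(row["age"]),
                district_id=str(row["district_id"]),
                address_id=str(row["address_id"]),
                household_id=str(row["household_id"]),
                marital_satisfaction=None
                if satisfaction is None
                else int(float(satisfaction)),
                reports_any_confidant=None if reports is None else bool(reports),
                household_members=members_by_id.get(pid, []),
                community_nominations=noms_by_id.get(pid, []),
                gds_items=None if any(g is None for g in gds) else [str(g) for g in gds],
                smc_items=None if any(s is None for s in smc) else smc,
                smc_severe_problem=None if severe is None else bool(severe),
                tmig_items=None if any(t is None for t in tmig) else tmig,
                education_years_band=str(row.get("education_years_band", "other")),
            )
        )
    return records


def write_survey(records: Sequence[ParticipantRecord], out_dir: PathLike) -> Dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    participants, members, nominations = records_to_tables(records)
    paths = {
        "participants": out / "participants.csv",
        "household_members": out / "household_members.csv",
        "nominations": out / "nominations.csv",
    }
    participants.to_csv(paths["participants"], index=False)
    members.to_csv(paths["household_members"], index=False)
    nominations.to_csv(paths["nominations"], index=False)
    return paths


def read_survey(survey_dir: PathLike) -> List[ParticipantRecord]:
    survey_dir = Path(survey_dir)
    participants = pd.read_csv(survey_dir / "participants.csv", dtype=object)
    members_path = survey_dir / "household_members.csv"
    nominations_path = survey_dir / "nominations.csv"
    members = pd.read_csv(members_path, dtype=object) if members_path.exists() else None
    nominations = (
        pd.read_csv(nominations_path, dtype=object) if nominations_path.exists() else None
    )
    return tables_to_records(participants, members, nominations)


def write_edge_list(network: DirectedNetwork, path: PathLike) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "source": i,
            "target": j,
            "provenance": network.tie_provenance.get((i, j), ""),
        }
        for (i, j) in sorted(network.edges)
    ]
    pd.DataFrame(rows, columns=["source", "target", "provenance"]).to_csv(
        path, sep="\t", index=False
    )
    return path


def read_edge_list(path: PathLike, nodes: Optional[Sequence] = None) -> DirectedNetwork:
    df = pd.read_csv(path, sep="\t", dtype=object)
    edges = [(r["source"], r["target"]) for _, r in df.iterrows()]
    provenance = {
        (r["source"], r["target"]): r["provenance"]
        for _, r in df.iterrows()
        if _opt(r.get("provenance"))
    }
    if nodes is None:
        seen = []
        for (i, j) in edges:
            for v in (i, j):
                if v not in seen:
                    seen.append(v)
        nodes = seen
    return from_edge_list(nodes, edges, tie_provenance=provenance)


def write_scored_table(records: Sequence[ParticipantRecord], path: PathLike) -> Path:
    """participant_id x (gds_total, apathy, suicidal_ideation, covariates)."""
    rows = []
    for r in records:
        scores = score_gds(r.gds_items)
        cov = code_covariates(r, scores)
        rows.append({"participant_id": r.participant_id, **cov.as_dict()})
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_node_attributes(path: PathLike) -> Dict[str, dict]:
    df = pd.read_csv(path)
    out: Dict[str, dict] = {}
    for _, row in df.iterrows():
        attrs = row.to_dict()
        pid = str(attrs.pop("participant_id"))
        out[pid] = {
            k: (None if pd.isna(v) else (int(v) if float(v).is_integer() else float(v)))
            for k, v in attrs.items()
        }
    return out


def write_match_report(report: MatchReport, path: PathLike) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for outcome in report.outcomes:
            fh.write(json.dumps(outcome.as_dict(), ensure_ascii=False) + "\n")
        for pid, name in report.unresolved_household_members:
            fh.write(
                json.dumps(
                    {
                        "nominator_id": pid,
                        "status": "unresolved_household_member",
                        "nominated_name": name,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )
    return path


def write_graphml(network: DirectedNetwork, path: PathLike) -> Path:
    """GraphML export with node attributes, for external visualization."""
    import networkx as nx

    g = network.to_networkx()
    for _, attrs in g.nodes(data=True):
        for k in list(attrs):
            if attrs[k] is None:
                del attrs[k]
    for _, _, attrs in g.edges(data=True):
        for k in list(attrs):
            if attrs[k] is None:
                del attrs[k]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nx.write_graphml(g, path)
    return path
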
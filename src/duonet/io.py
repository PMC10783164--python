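"""Read and write the tabular interview formats.

Three UTF-8 CSVs with header rows describe a cohort:

``alters.csv``
    one row per (couple, ego, alter): name key, spouse flag, relation flags
    (semicolon-joined), ego-alter knowing, relationship-quality items and
    contact-frequency codes, plus optional ``demo_*`` columns.
``ties.csv``
    long-format alter-alter ratings, one row per rated pair (upper triangle
    sufficient): couple_id, ego_role, alter_index_a, alter_index_b, rating.
    Pairs absent from the table are treated as 0 ("no contact") and counted.
``couples.csv``
    per-couple satisfaction scores and demographics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import (
    ALTERS_PER_EGO,
    AlterRecord,
    CoupleRecord,
    EgoInterview,
    tie_rating_from_label,
)

log = logging.getLogger(__name__)


class SchemaError(ValueError):
    """A required column is missing or malformed."""


class CompletenessError(ValueError):
    """An interview does not meet the minimum-completeness threshold."""


ALTER_COLUMNS = [
    "couple_id",
    "ego_role",
    "alter_index",
    "name_key",
    "is_spouse",
    "relation_flags",
    "knowing",
    "relationship_rating",
    "tangible_support",
    "emotional_support",
    "marriage_opinion",
    "f2f_frequency",
    "virtual_frequency",
]
TIE_COLUMNS = ["couple_id", "ego_role", "alter_index_a", "alter_index_b", "rating"]
COUPLE_COLUMNS = ["couple_id", "wife_satisfaction", "husband_satisfaction"]

_TRUTHY = {"1", "true", "yes", "t"}
_FALSY = {"0", "false", "no", "f", ""}


def _as_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().casefold()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise SchemaError(f"unparseable boolean value: {value!r}")


def _require_columns(df: pd.DataFrame, required, table: str):
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{table}: missing required column(s) {missing}")


@dataclass
class LoadReport:
    """What the loader excluded or repaired, for the run ledger."""

    excluded: list = field(default_factory=list)  # (couple_id, reason)
    missing_pair_ratings: int = 0
    rejected_rows: list = field(default_factory=list)  # (table, couple_id, reason)


def _build_interview(couple_id, ego_role, alter_rows: pd.DataFrame, tie_rows: pd.DataFrame,
                     satisfaction: float, report: LoadReport) -> EgoInterview:
    alter_rows = alter_rows.sort_values("alter_index")
    alters = []
    for _, row in alter_rows.iterrows():
        flags = str(row["relation_flags"]) if pd.notna(row["relation_flags"]) else ""
        demographics = {
            c[len("demo_"):]: row[c]
            for c in alter_rows.columns
            if c.startswith("demo_") and pd.notna(row[c])
        }
        alters.append(
            AlterRecord(
                alter_index=int(row["alter_index"]),
                name_key=row["name_key"],
                is_spouse=_as_bool(row["is_spouse"]),
                relation_flags={f for f in flags.split(";") if f},
                knowing=tie_rating_from_label(row["knowing"]),
                relationship_rating=str(row["relationship_rating"]),
                tangible_support=_as_bool(row["tangible_support"]),
                emotional_support=_as_bool(row["emotional_support"]),
                marriage_opinion=str(row["marriage_opinion"]),
                f2f_frequency=str(row["f2f_frequency"]),
                virtual_frequency=str(row["virtual_frequency"]),
                demographics=demographics,
            )
        )
    n = len(alters)
    index_pos = {a.alter_index: k for k, a in enumerate(alters)}
    ties = np.zeros((n, n), dtype=int)
    rated = np.zeros((n, n), dtype=bool)
    for _, row in tie_rows.iterrows():
        ia, ib = int(row["alter_index_a"]), int(row["alter_index_b"])
        if ia not in index_pos or ib not in index_pos:
            report.rejected_rows.append(
                ("ties", couple_id, f"{ego_role}: tie references unknown alter index ({ia},{ib})")
            )
            continue
        a, b = index_pos[ia], index_pos[ib]
        r = tie_rating_from_label(row["rating"])
        ties[a, b] = ties[b, a] = r
        rated[a, b] = rated[b, a] = True
    np.fill_diagonal(rated, True)
    n_missing = int((~rated).sum() // 2)
    if n_missing:
        report.missing_pair_ratings += n_missing
        log.info("%s/%s: %d unrated alter pairs treated as no contact", couple_id, ego_role, n_missing)
    return EgoInterview(
        couple_id=str(couple_id),
        ego_role=ego_role,
        alters=alters,
        alter_ties=ties,
        satisfaction=float(satisfaction) if pd.notna(satisfaction) else np.nan,
    )


def load_couples(
    alter_table_path,
    tie_table_path,
    couple_table_path,
    min_alters: int = ALTERS_PER_EGO,
    on_incomplete: str = "raise",
    report: LoadReport | None = None,
) -> list[CoupleRecord]:
    """Load a cohort from the three CSV tables.

    A couple is constructed only when its couple_id appears in all three
    tables; rows referencing unknown couples are rejected into ``report``.
    Interviews naming fewer than ``min_alters`` alters either raise a
    :class:`CompletenessError` (default) or, with ``on_incomplete="exclude"``,
    drop the couple with a logged reason — interview protocols admit
    partially complete respondents, and the analysis threshold is a choice.
    """
    if on_incomplete not in ("raise", "exclude"):
        raise ValueError("on_incomplete must be 'raise' or 'exclude'")
    report = report if report is not None else LoadReport()

    alters = pd.read_csv(alter_table_path, dtype={"couple_id": str})
    ties = pd.read_csv(tie_table_path, dtype={"couple_id": str})
    couples = pd.read_csv(couple_table_path, dtype={"couple_id": str})
    _require_columns(alters, ALTER_COLUMNS, "alters.csv")
    _require_columns(ties, TIE_COLUMNS, "ties.csv")
    _require_columns(couples, COUPLE_COLUMNS, "couples.csv")

    known_ids = set(couples["couple_id"])
    for table_name, df in (("alters", alters), ("ties", ties)):
        unknown = sorted(set(df["couple_id"]) - known_ids)
        for cid in unknown:
            report.rejected_rows.append((table_name, cid, "couple_id absent from couples.csv"))
    alters = alters[alters["couple_id"].isin(known_ids)]
    ties = ties[ties["couple_id"].isin(known_ids)]

    alter_groups = dict(tuple(alters.groupby(["couple_id", "ego_role"], sort=True)))
    tie_groups = dict(tuple(ties.groupby(["couple_id", "ego_role"], sort=True)))
    empty_ties = ties.iloc[0:0]

    records: list[CoupleRecord] = []
    for _, crow in couples.sort_values("couple_id").iterrows():
        cid = crow["couple_id"]
        interviews = {}
        problem = None
        for role in ("wife", "husband"):
            rows = alter_groups.get((cid, role))
            if rows is None:
                problem = f"no alter rows for {role}"
                break
            if len(rows) < min_alters:
                problem = f"{role} named {len(rows)} alters, below threshold {min_alters}"
                break
            sat = crow.get(f"{role}_satisfaction", np.nan)
            interviews[role] = _build_interview(
                cid, role, rows, tie_groups.get((cid, role), empty_ties), sat, report
            )
        if problem is not None:
            if on_incomplete == "raise":
                raise CompletenessError(f"couple {cid}: {problem}")
            report.excluded.append((cid, problem))
            log.warning("excluding couple %s: %s", cid, problem)
            continue
        demo = {
            c: crow[c]
            for c in couples.columns
            if c not in ("couple_id", "wife_satisfaction", "husband_satisfaction")
            and pd.notna(crow[c])
        }
        records.append(
            CoupleRecord(couple_id=cid, wife=interviews["wife"], husband=interviews["husband"],
                         demographics=demo)
        )
    return records


def write_couples(records: list[CoupleRecord], alter_table_path, tie_table_path, couple_table_path):
    """Write a cohort back to the three CSV tables (inverse of load_couples)."""
    alter_rows, tie_rows, couple_rows = [], [], []
    for rec in records:
        for iv in (rec.wife, rec.husband):
            demo_cols = {}
            for a in iv.alters:
                row = {
                    "couple_id": rec.couple_id,
                    "ego_role": iv.ego_role,
                    "alter_index": a.alter_index,
                    "name_key": a.name_key,
                    "is_spouse": int(a.is_spouse),
                    "relation_flags": ";".join(sorted(a.relation_flags)),
                    "knowing": a.knowing,
                    "relationship_rating": a.relationship_rating,
                    "tangible_support": int(a.tangible_support),
                    "emotional_support": int(a.emotional_support),
                    "marriage_opinion": a.marriage_opinion,
                    "f2f_frequency": a.f2f_frequency,
                    "virtual_frequency": a.virtual_frequency,
                }
                for k, v in a.demographics.items():
                    row[f"demo_{k}"] = v
                    demo_cols[f"demo_{k}"] = True
                alter_rows.append(row)
            n = len(iv.alters)
            idx = [a.alter_index for a in iv.alters]
            for i in range(n):
                for j in range(i + 1, n):
                    r = int(iv.alter_ties[i, j])
                    if r:
                        tie_rows.append(
                            {
                                "couple_id": rec.couple_id,
                                "ego_role": iv.ego_role,
                                "alter_index_a": idx[i],
                                "alter_index_b": idx[j],
                                "rating": r,
                            }
                        )
        crow = {
            "couple_id": rec.couple_id,
            "wife_satisfaction": rec.wife.satisfaction,
            "husband_satisfaction": rec.husband.satisfaction,
        }
        crow.update(rec.demographics)
        couple_rows.append(crow)
    pd.DataFrame(alter_rows).to_csv(alter_table_path, index=False)
    pd.DataFrame(tie_rows, columns=TIE_COLUMNS).to_csv(tie_table_path, index=False)
    pd.DataFrame(couple_rows).to_csv(couple_table_path, index=False)
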
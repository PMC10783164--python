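"""Interview data model for paired spouse egocentric network interviews.

Each spouse ("ego") names their partner plus 24 further alters (25 in all),
flags how each alter is related to the couple, rates how well they know each
alter, answers relationship-quality items per alter, and rates how well every
pair of named alters knows each other on the ordinal scale

    0 = no contact, 1 = "Not Well", 2 = "Pretty Well", 3 = "Very Well".

The 0/1 distinction matters downstream: structural measures treat both "no
contact" and "Not Well" as absent ties, but the raw codes are preserved here.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field

import numpy as np

#: ordinal tie-rating codes
TIE_LABELS = {
    "no contact": 0,
    "not well": 1,
    "pretty well": 2,
    "very well": 3,
}
TIE_CODES = {v: k for k, v in TIE_LABELS.items()}

RELATION_FLAGS = frozenset(
    {
        "own_family",
        "spouse_family",
        "own_friend",
        "spouse_friend",
        "coworker",
        "neighbor",
        "other",
    }
)

RELATIONSHIP_RATINGS = ("good", "neutral", "bad")
MARRIAGE_OPINIONS = ("approve", "disapprove", "no_opinion")

#: number of alters elicited per ego (spouse + 24)
ALTERS_PER_EGO = 25

_PUNCT = re.compile(r"[^\w\s]", flags=re.UNICODE)
_WS = re.compile(r"\s+")


def normalize_name(name: str) -> str:
    """Normalize a free-text alter name into a deterministic matching key.

    Case-folds, strips accents-preserving punctuation, trims, and collapses
    internal whitespace, so that "María  López " and "maria lopez" do not
    accidentally diverge on formatting alone (accents are kept: they are
    name content, not formatting).
    """
    s = unicodedata.normalize("NFC", str(name)).casefold()
    s = _PUNCT.sub(" ", s)
    return _WS.sub(" ", s).strip()


def tie_rating_from_label(label) -> int:
    """Map an ordinal tie label (or an already-numeric code) to 0..3."""
    if isinstance(label, (int, np.integer)):
        value = int(label)
    else:
        key = str(label).strip().casefold()
        if key in TIE_LABELS:
            return TIE_LABELS[key]
        try:
            value = int(key)
        except ValueError:
            raise ValueError(f"unknown tie rating label: {label!r}") from None
    if value not in (0, 1, 2, 3):
        raise ValueError(f"tie rating out of range 0..3: {value}")
    return value


@dataclass
class AlterRecord:
    """One named alter and the ego's assessments of them."""

    alter_index: int  # 1..25 within one interview; 1 is conventionally the spouse
    name_key: str
    is_spouse: bool = False
    relation_flags: set = field(default_factory=set)
    specific_kin: str | None = None
    knowing: int = 1  # ego-alter knowing, 1..3 (an ego has contact with everyone named)
    relationship_rating: str = "good"
    tangible_support: bool = False
    emotional_support: bool = False
    marriage_opinion: str = "approve"
    f2f_frequency: str = "once a week"
    virtual_frequency: str = "once a week"
    demographics: dict = field(default_factory=dict)

    def __post_init__(self):
        self.name_key = normalize_name(self.name_key)
        self.relation_flags = set(self.relation_flags)


@dataclass
class EgoInterview:
    """One spouse's complete egocentric interview."""

    couple_id: str
    ego_role: str  # "wife" | "husband"
    alters: list  # ordered AlterRecords
    alter_ties: np.ndarray  # symmetric (n_alters, n_alters) ordinal matrix, diagonal unused
    satisfaction: float = np.nan

    @property
    def spouse_index(self) -> int | None:
        for a in self.alters:
            if a.is_spouse:
                return a.alter_index
        return None

    def alter_by_index(self, idx: int) -> AlterRecord:
        for a in self.alters:
            if a.alter_index == idx:
                return a
        raise KeyError(f"no alter with index {idx}")

    def tie(self, i: int, j: int) -> int:
        """Alter-alter rating between alter indices i and j (1-based)."""
        return int(self.alter_ties[i - 1, j - 1])


@dataclass
class CoupleRecord:
    couple_id: str
    wife: EgoInterview
    husband: EgoInterview
    demographics: dict = field(default_factory=dict)

    def ego(self, role: str) -> EgoInterview:
        if role == "wife":
            return self.wife
        if role == "husband":
            return self.husband
        raise ValueError(f"unknown ego role: {role!r}")


@dataclass
class ValidationReport:
    couple_id: str
    violations: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, msg: str):
        self.violations.append(msg)


def _validate_interview(iv: EgoInterview, report: ValidationReport, expected_alters: int):
    tag = f"{iv.ego_role}"
    if len(iv.alters) != expected_alters:
        report.add(f"{tag}: {len(iv.alters)} alters named, expected {expected_alters}")
    spouse_flags = sum(a.is_spouse for a in iv.alters)
    if spouse_flags != 1:
        report.add(f"{tag}: {spouse_flags} alters flagged is_spouse, expected exactly 1")
    seen = set()
    for a in iv.alters:
        if a.alter_index in seen:
            report.add(f"{tag}: duplicate alter_index {a.alter_index}")
        seen.add(a.alter_index)
        if not 1 <= a.knowing <= 3:
            report.add(f"{tag}: alter {a.alter_index} knowing rating {a.knowing} outside 1..3")
        bad_flags = a.relation_flags - RELATION_FLAGS
        if bad_flags:
            report.add(f"{tag}: alter {a.alter_index} unknown relation flags {sorted(bad_flags)}")
        if a.relationship_rating not in RELATIONSHIP_RATINGS:
            report.add(f"{tag}: alter {a.alter_index} relationship rating {a.relationship_rating!r}")
        if a.marriage_opinion not in MARRIAGE_OPINIONS:
            report.add(f"{tag}: alter {a.alter_index} marriage opinion {a.marriage_opinion!r}")
    ties = np.asarray(iv.alter_ties)
    n = len(iv.alters)
    if ties.shape != (n, n):
        report.add(f"{tag}: tie matrix shape {ties.shape}, expected ({n}, {n})")
        return
    asym = np.argwhere(ties != ties.T)
    for i, j in asym:
        if i < j:
            report.add(f"{tag}: asymmetry at ({i + 1},{j + 1})")
    off = ~np.eye(n, dtype=bool)
    out = np.argwhere(((ties < 0) | (ties > 3)) & off)
    for i, j in out:
        if i < j:
            report.add(f"{tag}: tie rating {ties[i, j]} at ({i + 1},{j + 1}) outside 0..3")


def validate_couple(record: CoupleRecord, expected_alters: int = ALTERS_PER_EGO) -> ValidationReport:
    """Check all interview invariants; returns a report, never raises.

    The report is empty iff the couple's two interviews are complete (25
    alters each, one spouse flag), tie matrices are symmetric with ratings in
    0..3, and every categorical item uses a known level.
    """
    report = ValidationReport(record.couple_id)
    if record.wife.couple_id != record.husband.couple_id:
        report.add("couple_id mismatch between spouse interviews")
    if record.wife.ego_role == record.husband.ego_role:
        report.add("spouse interviews share the same ego role")
    _validate_interview(record.wife, report, expected_alters)
    _validate_interview(record.husband, report, expected_alters)
    return report
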
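"""Synthetic paired spouse interviews with planted archetype structure.

No interview data ship with this package, so every pipeline stage is
exercised on generated couples. The generator emits the exact tabular schema
the loader reads, with a ground-truth record (archetype label, shared-alter
identity map, planted block labels) that downstream tests use as an oracle.

Each couple is drawn from an *archetype*: a parameterization of
  - roster composition: how many of each ego's 24 non-spouse alters are own
    family, own friends, or other contacts, and how many alters both spouses
    nominate (with reciprocal relation flags on the shared ones);
  - tie structure: a core/periphery stochastic block pattern per ego — a
    random number of isolate alters with no ties, and a connected core whose
    pairs are tied ("Pretty Well"+) with an ego-specific probability;
  - relationship quality: per-item response probabilities and a
    contact-frequency distribution;
  - satisfaction: per-spouse normal means/SDs.

The five default archetypes mirror the couple-network types the typology is
built to recover — wife-friend-centered, extremely disconnected,
shared-friend-centered, wife-family-centered, husband-family-centered — and
the default mixture (46, 60, 27, 60, 14)/207 reproduces, in expectation, a
cohort mean alter-tie density of 0.20 and component count of 6.73. Tie
probabilities and isolate rates per archetype were calibrated once against
those targets and frozen (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .records import AlterRecord, CoupleRecord, EgoInterview

# ---------------------------------------------------------------------------
# archetype specification

#: roster block labels used in ground truth
BLOCKS = ("family", "friend", "other", "shared_family_h", "shared_family_w",
          "shared_friend", "shared_other")


@dataclass
class ArchetypeSpec:
    """All knobs defining one couple-network archetype."""

    name: str
    #: alters nominated by both spouses, split by kind (sums to the overlap)
    shared_h_family: int = 1
    shared_w_family: int = 1
    shared_friends: int = 0
    shared_other: int = 1
    #: each ego's solo alters (each triple sums to 24 − overlap)
    wife_solo_family: int = 6
    wife_solo_friend: int = 8
    wife_solo_other: int = 7
    husband_solo_family: int = 6
    husband_solo_friend: int = 8
    husband_solo_other: int = 7
    #: expected isolate count per ego (Poisson-drawn, solo alters only)
    wife_iso_mean: float = 2.0
    husband_iso_mean: float = 2.0
    #: P(tie rated >= "Pretty Well") between two core alters of one ego
    wife_core_p: float = 0.35
    husband_core_p: float = 0.35
    #: P(rating == "Very Well" | tie present)
    strong_share: float = 0.5
    #: P(rating == "Not Well") for non-tied core pairs
    weak_tie_p: float = 0.05
    #: ego's rating of (spouse, own solo alter) pairs, over ratings 0..3
    spouse_pair_dist: tuple = (0.15, 0.15, 0.35, 0.35)
    #: ego-alter knowing distribution over ratings (1, 2, 3)
    know_dist: tuple = (0.08, 0.30, 0.62)
    #: relationship rating distribution over (good, neutral, bad)
    relationship_dist: tuple = (0.79, 0.19, 0.02)
    tangible_p: float = 0.24
    emotional_p: float = 0.24
    #: marriage-opinion distribution over (approve, disapprove, no_opinion)
    opinion_dist: tuple = (0.87, 0.04, 0.09)
    #: contact-frequency distribution over FREQ_CODES (used for f2f and virtual)
    freq_dist: tuple = (0.10, 0.20, 0.25, 0.25, 0.10, 0.07, 0.02, 0.01)
    #: per-spouse satisfaction (mean, sd)
    husband_satisfaction: tuple = (43.3, 8.6)
    wife_satisfaction: tuple = (42.6, 8.6)
    #: jitter roster counts by ±1 per couple (kept on by default)
    jitter: bool = True

    @property
    def overlap(self) -> int:
        return self.shared_h_family + self.shared_w_family + self.shared_friends + self.shared_other

    def validate(self):
        solo_w = self.wife_solo_family + self.wife_solo_friend + self.wife_solo_other
        solo_h = self.husband_solo_family + self.husband_solo_friend + self.husband_solo_other
        if self.overlap > 24:
            raise ValueError(f"{self.name}: overlap {self.overlap} exceeds 24 alters per ego")
        if solo_w + self.overlap != 24 or solo_h + self.overlap != 24:
            raise ValueError(
                f"{self.name}: per-ego roster must total 24 non-spouse alters "
                f"(wife {solo_w + self.overlap}, husband {solo_h + self.overlap})"
            )
        for p in (self.wife_core_p, self.husband_core_p, self.strong_share,
                  self.weak_tie_p, self.tangible_p, self.emotional_p):
            if not 0 <= p <= 1:
                raise ValueError(f"{self.name}: probability {p} outside [0,1]")


FREQ_CODES = ("every day", "few times a week", "once a week", "few times a month",
              "once a month", "few times a year", "once a year", "never")

# Tie probabilities and isolate means below were calibrated once so that the
# default five-archetype mixture reproduces the cohort targets (mean alter
# density 0.20, mean components 6.73) while preserving each archetype's
# relative density/fragmentation/subgroup ordering; frozen thereafter.
DEFAULT_ARCHETYPES: dict[str, ArchetypeSpec] = {
    "wife_friend": ArchetypeSpec(
        name="wife_friend",
        shared_h_family=1, shared_w_family=1, shared_friends=0, shared_other=2,
        wife_solo_family=6, wife_solo_friend=11, wife_solo_other=3,
        husband_solo_family=6, husband_solo_friend=9, husband_solo_other=5,
        wife_iso_mean=3.156, husband_iso_mean=3.156,
        wife_core_p=0.3512, husband_core_p=0.5267,
        strong_share=0.50,
    ),
    "extreme_disconnection": ArchetypeSpec(
        name="extreme_disconnection",
        shared_h_family=1, shared_w_family=1, shared_friends=0, shared_other=1,
        wife_solo_family=8, wife_solo_friend=7, wife_solo_other=6,
        husband_solo_family=6, husband_solo_friend=10, husband_solo_other=5,
        wife_iso_mean=5.58, husband_iso_mean=5.58,
        wife_core_p=0.3447, husband_core_p=0.3016,
        strong_share=0.35,
        know_dist=(0.17, 0.38, 0.45),
        relationship_dist=(0.70, 0.27, 0.03),
        tangible_p=0.10, emotional_p=0.12,
        opinion_dist=(0.70, 0.10, 0.20),
        freq_dist=(0.06, 0.16, 0.24, 0.28, 0.14, 0.08, 0.03, 0.01),
    ),
    "shared_friends": ArchetypeSpec(
        name="shared_friends",
        shared_h_family=2, shared_w_family=1, shared_friends=3, shared_other=1,
        wife_solo_family=5, wife_solo_friend=1, wife_solo_other=11,
        husband_solo_family=8, husband_solo_friend=7, husband_solo_other=2,
        wife_iso_mean=1.264, husband_iso_mean=1.264,
        wife_core_p=0.4185, husband_core_p=0.3616,
        strong_share=0.50,
        emotional_p=0.40,
    ),
    "wife_family": ArchetypeSpec(
        name="wife_family",
        shared_h_family=2, shared_w_family=5, shared_friends=0, shared_other=2,
        wife_solo_family=7, wife_solo_friend=6, wife_solo_other=2,
        husband_solo_family=5, husband_solo_friend=5, husband_solo_other=5,
        wife_iso_mean=1.204, husband_iso_mean=1.204,
        wife_core_p=0.3688, husband_core_p=0.3434,
        strong_share=0.60,
        know_dist=(0.05, 0.25, 0.70),
        tangible_p=0.30, emotional_p=0.28,
        opinion_dist=(0.92, 0.02, 0.06),
    ),
    "husband_family": ArchetypeSpec(
        name="husband_family",
        shared_h_family=5, shared_w_family=1, shared_friends=0, shared_other=1,
        wife_solo_family=8, wife_solo_friend=5, wife_solo_other=4,
        husband_solo_family=12, husband_solo_friend=3, husband_solo_other=2,
        wife_iso_mean=0.903, husband_iso_mean=0.903,
        wife_core_p=0.5312, husband_core_p=0.7437,
        strong_share=0.60,
        know_dist=(0.05, 0.25, 0.70),
        tangible_p=0.30, emotional_p=0.28,
        opinion_dist=(0.92, 0.02, 0.06),
    ),
}

#: cluster-size mixture of the five archetypes
DEFAULT_MIXTURE = {
    "wife_friend": 46 / 207,
    "extreme_disconnection": 60 / 207,
    "shared_friends": 27 / 207,
    "wife_family": 60 / 207,
    "husband_family": 14 / 207,
}

RACE_CATEGORIES = ("latino", "black", "white", "other")
RACE_PROBS = (0.449, 0.299, 0.063, 0.189)

_FIRST = (
    "maria sofia lucia elena carmen rosa ana isabel laura marta james david daniel "
    "michael robert carlos jose luis miguel juan grace ruth naomi esther hannah "
    "kevin brian jason aaron derek tina wendy paula diane joyce victor hector omar "
    "felix ivan nina vera iris dora cleo amos cyril edgar floyd gus"
).split()
_LAST = (
    "lopez garcia martinez rodriguez hernandez smith johnson williams brown jones "
    "miller davis wilson anderson taylor thomas moore jackson martin lee perez "
    "thompson white harris clark lewis walker hall young king wright scott green "
    "adams baker nelson hill campbell mitchell roberts"
).split()


@dataclass
class CoupleGroundTruth:
    """What the generator planted, for use as a test oracle."""

    couple_id: str
    archetype: str
    #: identity map of shared alters: (wife_alter_index, husband_alter_index)
    shared_pairs: list
    #: per-ego block label by alter index, e.g. {"wife": {3: "friend", ...}}
    blocks: dict
    #: per-ego isolate alter indices
    isolates: dict


def _jittered_counts(spec: ArchetypeSpec, rng: np.random.Generator) -> ArchetypeSpec:
    """Perturb roster counts by ±1 against the 'other' bucket (totals kept)."""
    if not spec.jitter:
        return spec
    out = replace(spec)
    # overlap varies by ±1 via the shared-other bucket (both solo-other buckets
    # compensate, keeping each ego at 24 non-spouse alters)
    delta = int(rng.integers(-1, 2))
    if delta == -1 and out.shared_other >= 1:
        out.shared_other -= 1
        out.wife_solo_other += 1
        out.husband_solo_other += 1
    elif delta == 1 and out.wife_solo_other >= 1 and out.husband_solo_other >= 1:
        out.shared_other += 1
        out.wife_solo_other -= 1
        out.husband_solo_other -= 1
    for ego in ("wife", "husband"):
        for role in ("family", "friend"):
            delta = int(rng.integers(-1, 2))
            role_attr = f"{ego}_solo_{role}"
            other_attr = f"{ego}_solo_other"
            new_role = getattr(out, role_attr) + delta
            new_other = getattr(out, other_attr) - delta
            if new_role >= 0 and new_other >= 0:
                setattr(out, role_attr, new_role)
                setattr(out, other_attr, new_other)
    return out


def _draw_name(rng: np.random.Generator, used: set) -> str:
    while True:
        name = f"{rng.choice(_FIRST)} {rng.choice(_LAST)}"
        if name not in used:
            used.add(name)
            return name


def _categorical(rng, values, probs):
    return values[int(rng.choice(len(values), p=np.asarray(probs) / np.sum(probs)))]


def generate_couple(
    spec: ArchetypeSpec,
    couple_id: str,
    seed,
    name_noise: float = 0.0,
) -> tuple[CoupleRecord, CoupleGroundTruth]:
    """Generate one couple's pair of interviews, deterministically per seed.

    ``name_noise`` is the probability that a shared alter's name is perturbed
    on the husband's side (last name dropped), exercising matching-failure
    paths; 0 by default so exact name matching is a clean oracle.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    spec = _jittered_counts(spec, rng)

    used_names: set = set()
    wife_name = _draw_name(rng, used_names)
    husband_name = _draw_name(rng, used_names)

    # --- roster of unique non-spouse alters -------------------------------
    # entries: (name, nominators, wife_flags, husband_flags, block)
    roster = []

    def shared_entry(kind, w_flags, h_flags):
        roster.append({
            "name": _draw_name(rng, used_names), "nominated": "both",
            "wife_flags": w_flags, "husband_flags": h_flags, "block": kind,
        })

    for _ in range(spec.shared_h_family):
        shared_entry("shared_family_h", {"spouse_family"}, {"own_family"})
    for _ in range(spec.shared_w_family):
        shared_entry("shared_family_w", {"own_family"}, {"spouse_family"})
    for _ in range(spec.shared_friends):
        shared_entry("shared_friend", {"own_friend"}, {"own_friend"})
    for _ in range(spec.shared_other):
        shared_entry("shared_other", {"other"}, {"other"})

    def solo_entry(ego, kind, flags):
        roster.append({
            "name": _draw_name(rng, used_names), "nominated": ego,
            "wife_flags": flags if ego == "wife" else set(),
            "husband_flags": flags if ego == "husband" else set(),
            "block": kind,
        })

    for ego, fam, fri, oth in (
        ("wife", spec.wife_solo_family, spec.wife_solo_friend, spec.wife_solo_other),
        ("husband", spec.husband_solo_family, spec.husband_solo_friend, spec.husband_solo_other),
    ):
        for _ in range(fam):
            solo_entry(ego, "family", {"own_family"})
        for _ in range(fri):
            solo_entry(ego, "friend", {"own_friend"})
        for _ in range(oth):
            solo_entry(ego, "other", {_categorical(rng, ["coworker", "neighbor", "other"],
                                                   [0.4, 0.3, 0.3])})

    shared_demo_pool = [
        {"marital_status": _categorical(rng, ["married", "single"], [0.6, 0.4]),
         "has_children": _categorical(rng, ["yes", "no"], [0.5, 0.5]),
         "employed": _categorical(rng, ["yes", "no"], [0.7, 0.3])}
        for _ in roster
    ]

    # --- per-ego interviews -----------------------------------------------
    interviews = {}
    truth_blocks = {"wife": {}, "husband": {}}
    truth_iso = {"wife": [], "husband": []}
    index_of = {"wife": {}, "husband": {}}  # roster position -> alter index

    for ego in ("wife", "husband"):
        own = [k for k, e in enumerate(roster) if e["nominated"] in (ego, "both")]
        order = rng.permutation(len(own))
        own = [own[i] for i in order]

        solo_positions = [k for k in own if roster[k]["nominated"] == ego]
        n_iso = min(
            int(rng.poisson(spec.wife_iso_mean if ego == "wife" else spec.husband_iso_mean)),
            len(solo_positions),
        )
        iso_set = set(
            rng.choice(solo_positions, size=n_iso, replace=False).tolist() if n_iso else []
        )

        core_p = spec.wife_core_p if ego == "wife" else spec.husband_core_p
        know_levels = (1, 2, 3)
        alters = [
            AlterRecord(
                alter_index=1,
                name_key=husband_name if ego == "wife" else wife_name,
                is_spouse=True,
                relation_flags=set(),
                knowing=3,
                relationship_rating="good",
                tangible_support=True,
                emotional_support=True,
                marriage_opinion="approve",
                f2f_frequency="every day",
                virtual_frequency="every day",
            )
        ]
        for pos, k in enumerate(own, start=2):
            entry = roster[k]
            index_of[ego][k] = pos
            name = entry["name"]
            if name_noise and ego == "husband" and entry["nominated"] == "both":
                if rng.random() < name_noise:
                    name = name.split()[0]
            flags = entry["wife_flags"] if ego == "wife" else entry["husband_flags"]
            alters.append(
                AlterRecord(
                    alter_index=pos,
                    name_key=name,
                    is_spouse=False,
                    relation_flags=set(flags),
                    knowing=int(_categorical(rng, know_levels, spec.know_dist)),
                    relationship_rating=_categorical(rng, ["good", "neutral", "bad"],
                                                     spec.relationship_dist),
                    tangible_support=bool(rng.random() < spec.tangible_p),
                    emotional_support=bool(rng.random() < spec.emotional_p),
                    marriage_opinion=_categorical(rng, ["approve", "disapprove", "no_opinion"],
                                                  spec.opinion_dist),
                    f2f_frequency=_categorical(rng, FREQ_CODES, spec.freq_dist),
                    virtual_frequency=_categorical(rng, FREQ_CODES, spec.freq_dist),
                    demographics=dict(shared_demo_pool[k]) if entry["nominated"] == "both" else {},
                )
            )
            truth_blocks[ego][pos] = entry["block"]
            if k in iso_set:
                truth_iso[ego].append(pos)

        n = len(alters)
        ties = np.zeros((n, n), dtype=int)
        iso_indices = set(truth_iso[ego])
        for i in range(n):
            for j in range(i + 1, n):
                a, b = alters[i], alters[j]
                if a.is_spouse or b.is_spouse:
                    other = b if a.is_spouse else a
                    k_other = own[(other.alter_index - 2)]
                    if roster[k_other]["nominated"] == "both":
                        r = 3 if rng.random() < 0.7 else 2
                    elif other.alter_index in iso_indices:
                        r = int(_categorical(rng, (0, 1, 2, 3), (0.5, 0.3, 0.15, 0.05)))
                    else:
                        r = int(_categorical(rng, (0, 1, 2, 3), spec.spouse_pair_dist))
                elif a.alter_index in iso_indices or b.alter_index in iso_indices:
                    r = 0
                elif rng.random() < core_p:
                    r = 3 if rng.random() < spec.strong_share else 2
                else:
                    r = 1 if rng.random() < spec.weak_tie_p else 0
                ties[i, j] = ties[j, i] = r

        mean, sd = spec.wife_satisfaction if ego == "wife" else spec.husband_satisfaction
        interviews[ego] = EgoInterview(
            couple_id=str(couple_id),
            ego_role=ego,
            alters=alters,
            alter_ties=ties,
            satisfaction=float(np.clip(rng.normal(mean, sd), 10, 60)),
        )

    shared_pairs = sorted(
        (index_of["wife"][k], index_of["husband"][k])
        for k, e in enumerate(roster)
        if e["nominated"] == "both"
    )
    demographics = {
        "husband_age": round(float(np.clip(rng.normal(29.3, 7.3), 18, 70)), 1),
        "wife_age": round(float(np.clip(rng.normal(27.6, 6.9), 18, 70)), 1),
        "husband_edu": round(float(np.clip(rng.normal(13.7, 3.4), 6, 22)), 1),
        "wife_edu": round(float(np.clip(rng.normal(14.4, 3.3), 6, 22)), 1),
        "race_ethnicity": _categorical(rng, RACE_CATEGORIES, RACE_PROBS),
        "relationship_length_months": round(float(np.clip(rng.normal(4.82, 4.5), 0, 36)), 1),
    }
    record = CoupleRecord(
        couple_id=str(couple_id),
        wife=interviews["wife"],
        husband=interviews["husband"],
        demographics=demographics,
    )
    truth = CoupleGroundTruth(
        couple_id=str(couple_id),
        archetype=spec.name,
        shared_pairs=shared_pairs,
        blocks=truth_blocks,
        isolates=truth_iso,
    )
    return record, truth


def generate_cohort(
    n: int,
    mixture: dict | None = None,
    seed: int = 0,
    archetypes: dict | None = None,
    name_noise: float = 0.0,
) -> tuple[list[CoupleRecord], list[CoupleGroundTruth]]:
    """Draw ``n`` couples from a mixture over archetypes, deterministically."""
    mixture = DEFAULT_MIXTURE if mixture is None else mixture
    archetypes = DEFAULT_ARCHETYPES if archetypes is None else archetypes
    names = list(mixture)
    weights = np.array([mixture[k] for k in names], dtype=float)
    if weights.min() < 0 or not np.isclose(weights.sum(), 1.0):
        raise ValueError("mixture weights must be nonnegative and sum to 1")
    root = np.random.SeedSequence(seed)
    assign_rng = np.random.default_rng(root.spawn(1)[0])
    couple_seeds = root.spawn(n + 1)[1:]
    records, truths = [], []
    for i in range(n):
        label = names[int(assign_rng.choice(len(names), p=weights))]
        cid = f"c{i + 1:04d}"
        rec, truth = generate_couple(archetypes[label], cid, couple_seeds[i],
                                     name_noise=name_noise)
        records.append(rec)
        truths.append(truth)
    return records, truths


def truth_frame(truths: list[CoupleGroundTruth]) -> pd.DataFrame:
    rows = [
        {
            "couple_id": t.couple_id,
            "archetype": t.archetype,
            "shared_pairs": ";".join(f"{w}-{h}" for w, h in t.shared_pairs),
        }
        for t in truths
    ]
    return pd.DataFrame(rows, columns=["couple_id", "archetype", "shared_pairs"])


def write_cohort(records, truths, out_dir):
    """Emit the three interview CSVs plus ground_truth.csv into ``out_dir``."""
    from pathlib import Path

    from .io import write_couples

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_couples(records, out / "alters.csv", out / "ties.csv", out / "couples.csv")
    truth_frame(truths).to_csv(out / "ground_truth.csv", index=False)
    return out


def archetypes_to_yaml(path, archetypes: dict | None = None):
    """Dump archetype presets as YAML (editable, reloadable via from_yaml)."""
    import dataclasses

    import yaml

    specs = DEFAULT_ARCHETYPES if archetypes is None else archetypes
    payload = {name: dataclasses.asdict(spec) for name, spec in specs.items()}
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def archetypes_from_yaml(path) -> dict[str, ArchetypeSpec]:
    import yaml

    with open(path, encoding="utf-8") as fh:
        payload = yaml.safe_load(fh)
    out = {}
    for name, fields_ in payload.items():
        fields_ = {k: tuple(v) if isinstance(v, list) else v for k, v in fields_.items()}
        spec = ArchetypeSpec(**fields_)
        spec.validate()
        out[name] = spec
    return out
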
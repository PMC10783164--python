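"""Network relationship-quality measures and the combined couple score.

Quality proportions follow the same network-size denominator as the
compositional measures: counts of alters with a given response divided by the
full duocentric size *including both ego nodes*. Because egos sit in the
denominator but never a numerator, a category's proportions sum to the alter
share of the network (e.g. 48/50), not to 1 — deliberate, and worth knowing
before comparing levels across couples of different overlap.

For alters rated by both spouses, one value per item is formed before
counting: ordinal items take the more favorable rating (consistent with the
maximum rule used for tie merging), binary support items take logical OR, and
marriage-opinion takes the more favorable level under
approve > no_opinion > disapprove.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .merge import AlterMatching, DuocentricNetwork
from .records import EgoInterview

#: contact-frequency codes -> days per year (config-overridable)
DEFAULT_FREQUENCY_DAYS = {
    "every day": 365,
    "few times a week": 156,
    "once a week": 52,
    "few times a month": 36,
    "once a month": 12,
    "few times a year": 3,
    "once a year": 1,
    "never": 0,
}

_KNOW_ORDER = {1: 0, 2: 1, 3: 2}  # higher = knows better
_REL_ORDER = {"bad": 0, "neutral": 1, "good": 2}
_OPINION_ORDER = {"disapprove": 0, "no_opinion": 1, "approve": 2}


class FrequencyMapError(KeyError):
    """A contact-frequency code has no days-per-year mapping."""


@dataclass
class QualityProfile:
    couple_id: str
    know_very_well: float
    know_pretty_well: float
    know_not_well: float
    relationship_good: float
    relationship_neutral: float
    relationship_bad: float
    tangible_support: float
    emotional_support: float
    approve: float
    disapprove: float
    no_opinion: float
    f2f_days: float
    virtual_days: float

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _reduce(values, order, combine):
    if len(values) == 1:
        return values[0]
    key = lambda v: order[v]
    if combine == "max":
        return max(values, key=key)
    if combine == "min":
        return min(values, key=key)
    # mean: round to the nearer level, favorable on ties
    ranks = [order[v] for v in values]
    target = int(np.floor(np.mean(ranks) + 0.5))
    inv = {r: v for v, r in order.items()}
    return inv[target]


def _days(code: str, freq_map: dict) -> float:
    try:
        return freq_map[code]
    except KeyError:
        raise FrequencyMapError(f"unknown contact-frequency code: {code!r}") from None


def quality_profile(
    net: DuocentricNetwork,
    wife: EgoInterview,
    husband: EgoInterview,
    matching: AlterMatching,
    combine: str = "max",
    frequency_days: dict | None = None,
) -> QualityProfile:
    """Per-couple relationship-quality proportions and contact-day means."""
    if combine not in ("max", "min", "mean"):
        raise ValueError("combine must be 'max', 'min', or 'mean'")
    freq_map = DEFAULT_FREQUENCY_DAYS if frequency_days is None else dict(frequency_days)

    matched_w = dict(matching.pairs)
    rev = {h: w for w, h in matching.pairs}
    records: dict[str, list] = {}
    for role, iv in (("wife", wife), ("husband", husband)):
        for a in iv.alters:
            if a.is_spouse:
                continue
            if role == "wife":
                node = (f"b{a.alter_index:02d}_{matched_w[a.alter_index]:02d}"
                        if a.alter_index in matched_w else f"w{a.alter_index:02d}")
            else:
                node = (f"b{rev[a.alter_index]:02d}_{a.alter_index:02d}"
                        if a.alter_index in rev else f"h{a.alter_index:02d}")
            records.setdefault(node, []).append(a)

    size = net.size
    counts = {
        "know_very_well": 0, "know_pretty_well": 0, "know_not_well": 0,
        "relationship_good": 0, "relationship_neutral": 0, "relationship_bad": 0,
        "tangible_support": 0, "emotional_support": 0,
        "approve": 0, "disapprove": 0, "no_opinion": 0,
    }
    f2f_total = 0.0
    virtual_total = 0.0
    for node in net.alter_nodes():
        recs = records.get(node, [])
        if not recs:
            continue
        knowing = _reduce([a.knowing for a in recs], _KNOW_ORDER, combine)
        counts[{3: "know_very_well", 2: "know_pretty_well", 1: "know_not_well"}[knowing]] += 1
        rel = _reduce([a.relationship_rating for a in recs], _REL_ORDER, combine)
        counts[f"relationship_{rel}"] += 1
        if combine == "min":
            tangible = all(a.tangible_support for a in recs)
            emotional = all(a.emotional_support for a in recs)
        else:
            tangible = any(a.tangible_support for a in recs)
            emotional = any(a.emotional_support for a in recs)
        counts["tangible_support"] += tangible
        counts["emotional_support"] += emotional
        opinion = _reduce([a.marriage_opinion for a in recs], _OPINION_ORDER, combine)
        counts[opinion] += 1
        f2f_total += max(_days(a.f2f_frequency, freq_map) for a in recs)
        virtual_total += max(_days(a.virtual_frequency, freq_map) for a in recs)

    return QualityProfile(
        couple_id=net.couple_id,
        **{k: v / size for k, v in counts.items()},
        f2f_days=f2f_total / size,
        virtual_days=virtual_total / size,
    )


def couple_satisfaction_score(h: float, w: float, k: float = 0.5) -> float:
    """Difference-penalized combination of the two spouses' satisfaction.

        C = (h + w)/2 - k * |h - w| / 2,    0 <= k <= 1

    k = 0 gives the spouses' mean, k = 1 the lower of the two scores; the
    default k = 0.5 sits halfway, discounting couples who disagree about the
    relationship.
    """
    if not 0 <= k <= 1:
        raise ValueError(f"k must lie in [0, 1], got {k}")
    return (h + w) / 2 - k * abs(h - w) / 2
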
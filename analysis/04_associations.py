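"""Test associations between network type and couple covariates.

Merges the two family-centered clusters into a single Family group (they
profile alike and the husband-family group is small), rescales covariates to
interpretable units (proportions as deciles, constraint x100), and fits the
one-vs-rest logistic models plus the multinomial contrasts for constraint.
Writes results/associations.csv.
"""

import json
from pathlib import Path

import pandas as pd

from duonet.association import (
    association_table,
    covariate_table,
    merge_family_clusters,
    multinomial_logit,
)
from duonet.pipeline import DEFAULT_ASSOCIATION_COVARIATES

ROOT = Path(__file__).resolve().parent.parent / "results"

profiles = pd.read_csv(ROOT / "profiles.csv", index_col="couple_id")
quality = pd.read_csv(ROOT / "quality.csv", index_col="couple_id")
couples = pd.read_csv(ROOT / "data" / "couples.csv", index_col="couple_id")
demo = couples.drop(columns=["wife_satisfaction", "husband_satisfaction"])
bundle = json.loads((ROOT / "typology.json").read_text())
labels = pd.Series(bundle["labels"]).rename("cluster")
labels.index.name = "couple_id"

# name clusters by their dominant planted archetype, then join the family pair
truth = pd.read_csv(ROOT / "data" / "ground_truth.csv", index_col="couple_id")
names = {}
for c in sorted(labels.unique()):
    members = labels[labels == c].index
    names[c] = truth.loc[members, "archetype"].mode().iloc[0]
named = labels.map(names)
merged = merge_family_clusters(named, {"wife_family": "family", "husband_family": "family"})
print("cluster groups for modeling:", merged.value_counts().to_dict())

table = covariate_table(profiles, quality, demo)
covariates = [c for c in DEFAULT_ASSOCIATION_COVARIATES if c in table.columns]
covariates += [c for c in table.columns if c.startswith("race_")]
assoc = association_table(table, merged, covariates)
assoc.to_csv(ROOT / "associations.csv", index=False)

sig = assoc[(assoc["p"] < 0.05) & ~assoc["separation"]]
print(f"\n{len(sig)} covariate-cluster associations at p < .05:")
print(sig.round(3).to_string(index=False))

print("\nmultinomial contrasts for husband constraint (reference: family):")
out = multinomial_logit(merged.loc[table.index], table["husband_constraint"],
                        reference="family")
print(out[["rrr", "p"]].round(3).to_string())
print(f"\nwrote {ROOT / 'associations.csv'}")
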
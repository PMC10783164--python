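"""End-to-end orchestration: load/simulate -> merge -> measure -> cluster -> associate.

One :class:`RunConfig` drives a fully deterministic run: a single root seed
fans out to fixed per-stage offsets (generation, clustering, diagnostics) so
stages can be re-run in isolation and two identical configs produce
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, merge, quality, synthetic, typology
from .io import LoadReport, load_couples
from .measures import criterion_profile
from .quality import couple_satisfaction_score
from .records import validate_couple

log = logging.getLogger("duonet.pipeline")

# per-stage seed offsets off the root seed
SEED_GENERATE = 0
SEED_CLUSTER = 101
SEED_DIAGNOSTICS = 202


@dataclass
class RunConfig:
    out_dir: str = "duonet_run"
    #: either input CSV paths ...
    alters_csv: str | None = None
    ties_csv: str | None = None
    couples_csv: str | None = None
    #: ... or a synthetic cohort
    synthetic_n: int | None = None
    combine: str = "max"
    density_threshold: int = 2
    constraint_threshold: int = 3
    min_alters: int = 25
    k: int | str = "auto"
    k_range: tuple = (2, 8)
    seed: int = 0
    cluster_method: str = "ward_then_kmeans"
    satisfaction_k: float = 0.5
    decile_proportions: bool = True
    scale_constraint: bool = True
    export_graphml: bool = False
    name_noise: float = 0.0

    def validate(self):
        if self.combine not in ("max", "min", "mean"):
            raise ValueError("combine must be max/min/mean")
        for t in (self.density_threshold, self.constraint_threshold):
            if t not in (1, 2, 3):
                raise ValueError("tie thresholds must be in {1,2,3}")
        has_files = all(p is not None for p in (self.alters_csv, self.ties_csv, self.couples_csv))
        if not has_files and self.synthetic_n is None:
            raise ValueError("config needs either the three CSV paths or synthetic_n")


def build_couple_networks(records, combine="max"):
    """Match, merge, and role-classify every couple; yields (record, matching, net)."""
    out = []
    for rec in records:
        matching = merge.match_alters(rec.wife, rec.husband)
        net = merge.merge_to_duocentric(rec.wife, rec.husband, matching, combine=combine)
        merge.classify_roles(net, rec.wife, rec.husband, matching)
        out.append((rec, matching, net))
    return out


def profiles_table(built, density_threshold=2, constraint_threshold=3) -> pd.DataFrame:
    rows = [
        criterion_profile(net, density_threshold, constraint_threshold).as_dict()
        for _, _, net in built
    ]
    return pd.DataFrame(rows).set_index("couple_id")


def quality_table(built, combine="max", satisfaction_k=0.5) -> pd.DataFrame:
    rows = []
    for rec, matching, net in built:
        qp = quality.quality_profile(net, rec.wife, rec.husband, matching, combine=combine)
        row = qp.as_dict()
        row["husband_satisfaction"] = rec.husband.satisfaction
        row["wife_satisfaction"] = rec.wife.satisfaction
        row["couple_satisfaction"] = couple_satisfaction_score(
            rec.husband.satisfaction, rec.wife.satisfaction, k=satisfaction_k
        )
        rows.append(row)
    return pd.DataFrame(rows).set_index("couple_id")


def demographics_table(records) -> pd.DataFrame:
    rows = [{"couple_id": r.couple_id, **r.demographics} for r in records]
    return pd.DataFrame(rows).set_index("couple_id")


DEFAULT_ASSOCIATION_COVARIATES = [
    "husband_age", "wife_age", "husband_edu", "wife_edu",
    "husband_satisfaction", "wife_satisfaction", "couple_satisfaction",
    "relationship_length_months",
    "husband_constraint", "wife_constraint",
    "know_very_well", "relationship_good", "tangible_support", "emotional_support",
    "approve", "f2f_days", "virtual_days",
]


def run(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the results bundle (also on disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root_logger = logging.getLogger("duonet")
    root_logger.addHandler(handler)
    root_logger.setLevel(logging.INFO)
    try:
        return _run_stages(config, out)
    finally:
        root_logger.removeHandler(handler)
        handler.close()


def _run_stages(config: RunConfig, out: Path) -> dict:
    log.info("resolved config: %s", dataclasses.asdict(config))
    load_report = LoadReport()
    if config.synthetic_n is not None:
        log.info("stage simulate: n=%d seed=%d", config.synthetic_n, config.seed + SEED_GENERATE)
        records, truths = synthetic.generate_cohort(
            config.synthetic_n, seed=config.seed + SEED_GENERATE, name_noise=config.name_noise
        )
        synthetic.truth_frame(truths).to_csv(out / "ground_truth.csv", index=False)
    else:
        log.info("stage load: %s", config.alters_csv)
        records = load_couples(
            config.alters_csv, config.ties_csv, config.couples_csv,
            min_alters=config.min_alters, on_incomplete="exclude", report=load_report,
        )
        for cid, reason in load_report.excluded:
            log.warning("excluded couple %s: %s", cid, reason)
    for rec in records:
        report = validate_couple(rec)
        if not report.ok:
            raise ValueError(f"stage validate: couple {rec.couple_id}: {report.violations}")

    log.info("stage merge: %d couples, combine=%s", len(records), config.combine)
    built = build_couple_networks(records, combine=config.combine)
    if config.export_graphml:
        gml_dir = out / "graphml"
        gml_dir.mkdir(exist_ok=True)
        for _, _, net in built:
            merge.export_graphml(net, gml_dir / f"{net.couple_id}.graphml")

    log.info("stage measures")
    profiles = profiles_table(built, config.density_threshold, config.constraint_threshold)
    profiles.to_csv(out / "profiles.csv")
    qual = quality_table(built, combine=config.combine, satisfaction_k=config.satisfaction_k)
    qual.to_csv(out / "quality.csv")
    demo = demographics_table(records)

    log.info("stage typology")
    z = typology.standardize(profiles)
    diagnostics = typology.select_k(
        z, k_range=range(config.k_range[0], config.k_range[1] + 1),
        seed=config.seed + SEED_DIAGNOSTICS,
    )
    k = diagnostics.attrs["majority_k"] if config.k == "auto" else int(config.k)
    result = typology.run_typology(profiles, k=k, method=config.cluster_method,
                                   seed=config.seed + SEED_CLUSTER)
    _, lk = typology.ward_cluster(z, k)
    (out / "dendrogram.newick").write_text(typology.linkage_to_newick(lk, z.index))
    typology.plot_tscores(result.tscores, out / "tscores.png")

    log.info("stage association: k=%d", k)
    table = association.covariate_table(
        profiles, qual, demo,
        decile_proportions=config.decile_proportions,
        scale_constraint=config.scale_constraint,
    )
    covariates = [c for c in DEFAULT_ASSOCIATION_COVARIATES if c in table.columns]
    covariates += [c for c in table.columns if c.startswith("race_")]
    assoc = association.association_table(table, result.labels, covariates)
    assoc.to_csv(out / "associations.csv", index=False)

    bundle = {
        "k": k,
        "labels": {str(i): int(v) for i, v in result.labels.items()},
        "diagnostics": json.loads(diagnostics.drop(columns=[], errors="ignore").to_json(orient="index")),
        "majority_k": diagnostics.attrs["majority_k"],
        "tscores": json.loads(result.tscores.to_json(orient="index")),
        "anova": json.loads(result.anova.to_json(orient="index")),
        "excluded_couples": load_report.excluded + (result.excluded or []),
    }
    with open(out / "typology.json", "w") as fh:
        json.dump(bundle, fh, indent=2, sort_keys=True)
    log.info("run complete: %s", out)
    return {
        "records": records,
        "built": built,
        "profiles": profiles,
        "quality": qual,
        "demographics": demo,
        "diagnostics": diagnostics,
        "typology": result,
        "associations": assoc,
        "out_dir": out,
    }
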
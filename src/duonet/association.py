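"""Associations between network type and couple covariates.

Bivariate logistic models regress membership in one cluster (vs. all others)
on a single covariate; multinomial models over the full label set give the
pairwise cluster contrasts as relative risk ratios. Covariates enter on
interpretable scales: proportions as deciles (x10, so an odds ratio is per
10-percentage-point change) and Burt constraint x100 (per 0.01). Because the
smallest clusters can perfectly separate on a covariate, fits carry a
separation flag instead of failing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

#: covariates stored as proportions, rescaled to deciles for modeling
PROPORTION_COVARIATES = [
    "know_very_well", "relationship_good", "tangible_support", "emotional_support",
    "approve",
]
CONSTRAINT_COVARIATES = ["husband_constraint", "wife_constraint"]

#: |coefficient| or Wald SE beyond these bounds marks (quasi-)complete separation
SEPARATION_COEF = 15.0
SEPARATION_SE = 1e3


@dataclass
class LogitResult:
    covariate: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    coef: float
    se: float
    separation: bool = False


def merge_family_clusters(labels: pd.Series, merge_map: dict) -> pd.Series:
    """Relabel clusters per ``merge_map`` (e.g. join the two family types).

    Every key must be a current label; values are the replacement labels.
    """
    present = set(labels.unique())
    unknown = set(merge_map) - present
    if unknown:
        raise ValueError(f"merge_map source label(s) not present: {sorted(unknown)}")
    return labels.replace(merge_map)


def _fit_logit(y: np.ndarray, x: np.ndarray):
    exog = sm.add_constant(x, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(y, exog)
        try:
            res = model.fit(method="newton", disp=0, tol=1e-10, maxiter=200)
        except Exception:
            res = model.fit(method="bfgs", disp=0, maxiter=500)
    return res


def binary_logit(y, x, name: str = "x") -> LogitResult:
    """Maximum-likelihood logistic fit of membership on one covariate.

    Returns the odds ratio with its Wald 95% CI and p-value. Perfect or
    quasi-complete separation is flagged (diverging coefficient), not raised.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    classes = np.unique(y)
    if not np.array_equal(classes, [0.0, 1.0]):
        raise ValueError("y must contain both classes 0 and 1")
    if not np.all(np.isfinite(x)):
        raise ValueError("covariate contains non-finite values")
    if np.ptp(x[y == 1]) == 0 and np.ptp(x[y == 0]) == 0 and x[y == 1][0] == x[y == 0][0]:
        # covariate constant everywhere: no association by construction
        return LogitResult(name, 1.0, np.nan, np.nan, 1.0, 0.0, np.inf)
    res = _fit_logit(y, x)
    coef = res.params[1]
    se = res.bse[1]
    separation = abs(coef) > SEPARATION_COEF or se > SEPARATION_SE or not np.isfinite(se)
    ci = res.conf_int()[1]
    with np.errstate(over="ignore"):  # separated fits can push the CI to inf
        exp_ci = np.exp(ci)
    return LogitResult(
        covariate=name,
        odds_ratio=float(np.exp(coef)),
        ci_low=float(exp_ci[0]),
        ci_high=float(exp_ci[1]),
        p=float(res.pvalues[1]),
        coef=float(coef),
        se=float(se),
        separation=bool(separation),
    )


def multinomial_logit(labels, x, reference) -> pd.DataFrame:
    """Multinomial logistic fit of cluster membership on one covariate.

    Returns one row per non-reference class with the relative risk ratio
    (RRR) of that class vs. the reference per unit of ``x``, its Wald p, and
    a separation flag. Refit with each class as reference to obtain all
    pairwise contrasts; RRR(A vs B) = 1 / RRR(B vs A).
    """
    labels = pd.Series(labels).astype(str).reset_index(drop=True)
    x = np.asarray(x, dtype=float)
    classes = sorted(labels.unique())
    if str(reference) not in classes:
        raise ValueError(f"reference {reference!r} not among labels {classes}")
    if len(classes) < 2:
        raise ValueError("need at least 2 label classes")
    # order endog codes so the reference is category 0 (MNLogit's base)
    ordered = [str(reference)] + [c for c in classes if c != str(reference)]
    codes = labels.map({c: i for i, c in enumerate(ordered)}).to_numpy()
    exog = sm.add_constant(x, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MNLogit(codes, exog)
        try:
            res = model.fit(method="newton", disp=0, gtol=1e-10, maxiter=200)
        except Exception:
            res = model.fit(method="bfgs", disp=0, maxiter=500)
    rows = []
    for j, cls in enumerate(ordered[1:]):
        coef = res.params[1, j]
        se = res.bse[1, j]
        rows.append({
            "cluster": cls,
            "reference": str(reference),
            "rrr": float(np.exp(coef)),
            "p": float(res.pvalues[1, j]),
            "coef": float(coef),
            "se": float(se),
            "separation": bool(abs(coef) > SEPARATION_COEF or se > SEPARATION_SE
                               or not np.isfinite(se)),
        })
    return pd.DataFrame(rows).set_index("cluster")


def covariate_table(
    profiles: pd.DataFrame,
    quality: pd.DataFrame,
    demographics: pd.DataFrame,
    decile_proportions: bool = True,
    scale_constraint: bool = True,
    race_reference: str = "latino",
) -> pd.DataFrame:
    """Join and transform covariates into a model-ready table.

    Proportions are multiplied by 10 (decile units), constraint by 100, and
    race/ethnicity expands into dummies against the reference category. All
    three inputs must be indexed by couple_id and cover the same couples.
    """
    for name, df in (("quality", quality), ("demographics", demographics)):
        orphans = sorted(set(profiles.index).symmetric_difference(df.index))
        if orphans:
            raise ValueError(f"couple_id mismatch with {name} table: {orphans[:10]}")
    table = profiles.join(quality, how="inner", rsuffix="_q").join(
        demographics, how="inner", rsuffix="_d"
    )
    if decile_proportions:
        for col in PROPORTION_COVARIATES:
            if col in table:
                table[col] = table[col] * 10
    if scale_constraint:
        for col in CONSTRAINT_COVARIATES:
            if col in table:
                table[col] = table[col] * 100
    if "race_ethnicity" in table:
        cats = [c for c in table["race_ethnicity"].astype(str).unique() if c != race_reference]
        for cat in sorted(cats):
            table[f"race_{cat}"] = (table["race_ethnicity"].astype(str) == cat).astype(int)
        table = table.drop(columns=["race_ethnicity"])
    return table


def association_table(
    table: pd.DataFrame,
    labels: pd.Series,
    covariates,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """One-vs-rest logistic results for every (covariate, cluster) pair.

    No multiplicity correction by default (the analysis is exploratory);
    ``bh_correct`` applies Benjamini–Hochberg across the table.
    """
    labels = labels.loc[table.index]
    rows = []
    for cluster in sorted(labels.unique(), key=str):
        y = (labels == cluster).astype(int).to_numpy()
        for cov in covariates:
            res = binary_logit(y, table[cov].to_numpy(), name=cov)
            rows.append({
                "covariate": cov,
                "cluster": cluster,
                "odds_ratio": res.odds_ratio,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "p": res.p,
                "separation": res.separation,
            })
    out = pd.DataFrame(rows)
    if bh_correct and len(out):
        from statsmodels.stats.multitest import multipletests

        out["p_adj"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out
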
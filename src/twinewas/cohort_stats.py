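"""Descriptive cohort statistics and secondary tests.

Covers the two supporting analyses of the twin study design: comparing
birth-weight discordance between the young and old recruitment waves
(Welch two-sample t test), and testing whether extremely discordant pairs
(dbw% >= 25) are enriched for preterm birth (gestational age <= 37 weeks)
with a Pearson chi-square on the 2x2 pair counts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import TwinCohort, ValidationError
from .ewas import compute_dbw_pct

__all__ = [
    "chisq_2x2",
    "preterm_enrichment",
    "welch_t",
    "cohort_summary",
]

PRETERM_GA_THRESHOLD = 37.0
EXTREME_DBW_THRESHOLD = 25.0


def chisq_2x2(table) -> tuple:
    """Pearson chi-square (no continuity correction) for a 2x2 count table.

    Returns ``(statistic, p_value)`` with p from chi-square on 1 df.
    """
    t = np.asarray(table, float)
    if t.shape != (2, 2):
        raise ValidationError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise ValidationError("counts must be non-negative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValidationError("2x2 table has a zero margin")
    stat, p, dof, _ = stats.chi2_contingency(t, correction=False)
    return float(stat), float(p)


def preterm_enrichment(cohort: TwinCohort, ga_threshold: float = PRETERM_GA_THRESHOLD,
                       dbw_threshold: float = EXTREME_DBW_THRESHOLD) -> dict:
    """Preterm (ga <= threshold) x extreme-discordance (dbw% >= threshold)
    contingency analysis over pairs with known gestational age.

    Returns a dict with the 2x2 table (rows: extreme / non-extreme;
    columns: preterm / term), chi-square result, per-stratum preterm
    percentages, and the number of pairs excluded for missing gestational
    age.
    """
    pairs = cohort.pairs().set_index("pair_id")
    dbw = compute_dbw_pct(cohort)
    ga = pairs["gestational_age"]
    known = ga.notna()
    if not known.any():
        raise ValidationError("gestational age missing for all pairs")
    dbw = dbw[known.to_numpy()]
    ga = ga[known]
    extreme = dbw >= dbw_threshold
    preterm = ga <= ga_threshold
    a = int((extreme.to_numpy() & preterm.to_numpy()).sum())
    b = int((extreme.to_numpy() & ~preterm.to_numpy()).sum())
    c = int((~extreme.to_numpy() & preterm.to_numpy()).sum())
    d = int((~extreme.to_numpy() & ~preterm.to_numpy()).sum())
    table = np.array([[a, b], [c, d]])
    stat, p = chisq_2x2(table)
    return {
        "table": table,
        "chisq": stat,
        "p_value": p,
        "preterm_pct_extreme": 100.0 * a / (a + b) if a + b else np.nan,
        "preterm_pct_rest": 100.0 * c / (c + d) if c + d else np.nan,
        "n_pairs_included": int(known.sum()),
        "n_pairs_missing_ga": int((~known).sum()),
    }


def welch_t(x, y) -> tuple:
    """Welch two-sample t test; returns ``(t, df, p)`` with
    Welch-Satterthwaite degrees of freedom."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("each group needs at least 2 values")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0 and np.mean(x) == np.mean(y):
        return 0.0, float(len(x) + len(y) - 2), 1.0
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def cohort_summary(cohort: TwinCohort, age_split: float = 45.0) -> dict:
    """Descriptive summary: age (min/max/median), pair counts by sex, birth
    weight (min/max/mean over individuals), dbw% (min/max/mean/median over
    pairs), gestational age (min/max/median), overall and per age wave.
    Empty strata are reported as None."""
    pairs = cohort.pairs()
    dbw = compute_dbw_pct(cohort)

    def _stratum(sel_pairs: pd.DataFrame, sel_dbw: pd.Series) -> dict | None:
        if len(sel_pairs) == 0:
            return None
        bw = np.concatenate([sel_pairs["bw_bigger"].to_numpy(float),
                             sel_pairs["bw_smaller"].to_numpy(float)])
        ga = sel_pairs["gestational_age"].dropna()
        return {
            "n_pairs": int(len(sel_pairs)),
            "age": {"min": float(sel_pairs["age"].min()), "max": float(sel_pairs["age"].max()),
                    "median": float(sel_pairs["age"].median())},
            "sex_pairs": {"male": int((sel_pairs["sex"] == "male").sum()),
                          "female": int((sel_pairs["sex"] == "female").sum())},
            "birth_weight": {"min": float(bw.min()), "max": float(bw.max()),
                             "mean": float(bw.mean())},
            "dbw_pct": {"min": float(sel_dbw.min()), "max": float(sel_dbw.max()),
                        "mean": float(sel_dbw.mean()), "median": float(sel_dbw.median())},
            "gestational_age": None if len(ga) == 0 else
                {"min": float(ga.min()), "max": float(ga.max()), "median": float(ga.median())},
        }

    young = pairs["age"] < age_split
    return {
        "all": _stratum(pairs, dbw),
        "young": _stratum(pairs[young], dbw[young.to_numpy()]),
        "old": _stratum(pairs[~young], dbw[(~young).to_numpy()]),
        "age_split": age_split,
    }
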
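"""Probe- and sample-level quality control.

Probe level: with one twin pair measured in technical replicates (4 DNA
samples per twin in the emulated design), each probe's variability is the
pooled within-twin residual standard deviation across the 8 replicates —
residuals are taken against each twin's own replicate mean, and the pooled
SD uses ``n_replicates - 2`` degrees of freedom.  Probes with SD strictly
above 0.05 (beta scale) are unstable.

Sample level: genome-wide intra-pair Pearson correlation per twin pair is
compared against an age-stratified pseudo-twin null (random pairs of
individuals from different true pairs within the same age group).  Pairs
whose correlation falls strictly below their group's empirical 2.5th
percentile are flagged as poor quality.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import MethylationMatrix, TwinCohort, ValidationError

__all__ = [
    "probe_replicate_se",
    "flag_unstable_probes",
    "pair_correlations",
    "pseudo_twin_null",
    "flag_bad_pairs",
    "QCReport",
    "SE_THRESHOLD",
    "AGE_SPLIT",
]

SE_THRESHOLD = 0.05
AGE_SPLIT = 45.0  # < split -> young, >= split -> old
NULL_REPLICATES = 10_000


def probe_replicate_se(replicates: MethylationMatrix, replicate_map: dict) -> pd.DataFrame:
    """Pooled within-twin replicate SD per probe.

    ``replicate_map`` maps each replicate sample id to its twin id; exactly
    two twins are expected, each with at least two replicates.  Masked cells
    are excluded (degrees of freedom adjusted accordingly).

    Returns a DataFrame indexed by probe with column ``replicate_se``.
    """
    ids = list(replicates.sample_ids)
    missing = [s for s in ids if s not in replicate_map]
    if missing:
        raise ValidationError(f"samples without a replicate-map entry: {missing}")
    twins = pd.Series({s: replicate_map[s] for s in ids})
    groups = twins.groupby(twins).groups
    if len(groups) != 2:
        raise ValidationError(f"expected replicates of exactly 2 twins, got {len(groups)}")
    for t, members in groups.items():
        if len(members) < 2:
            raise ValidationError(f"twin {t!r} has fewer than 2 replicates")

    vals = replicates.masked_values().to_numpy(float)
    ss = np.zeros(vals.shape[0])
    n_valid = np.zeros(vals.shape[0])
    for members in groups.values():
        cols = [ids.index(s) for s in members]
        sub = vals[:, cols]
        mean = np.nanmean(sub, axis=1, keepdims=True)
        resid = sub - mean
        ss += np.nansum(resid**2, axis=1)
        n_valid += np.sum(~np.isnan(sub), axis=1)
    df = n_valid - 2  # two twin means estimated
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(np.where(df > 0, ss / np.maximum(df, 1), np.nan))
    return pd.DataFrame({"replicate_se": se}, index=replicates.probe_ids)


def flag_unstable_probes(probe_qc: pd.DataFrame, se_threshold: float = SE_THRESHOLD) -> list:
    """Probe ids with replicate SE strictly above ``se_threshold``."""
    se = probe_qc["replicate_se"]
    return list(probe_qc.index[se > se_threshold])


def pair_correlations(matrix: MethylationMatrix, cohort: TwinCohort,
                      min_overlap: int = 3) -> pd.DataFrame:
    """Genome-wide Pearson correlation between the twins of each pair.

    Computed over probes unmasked in both twins.  Pairs with fewer than
    ``min_overlap`` shared probes get a missing correlation and a warning.

    Returns a DataFrame with columns ``pair_id, age, age_group, correlation``.
    """
    pairs = cohort.pairs()
    vals = matrix.masked_values()
    rows = []
    for row in pairs.itertuples(index=False):
        a = vals[row.bigger].to_numpy()
        b = vals[row.smaller].to_numpy()
        ok = ~np.isnan(a) & ~np.isnan(b)
        if ok.sum() < min_overlap:
            warnings.warn(f"pair {row.pair_id}: only {int(ok.sum())} shared unmasked probes")
            r = np.nan
        else:
            r = float(np.corrcoef(a[ok], b[ok])[0, 1])
        rows.append({"pair_id": row.pair_id, "age": row.age,
                     "age_group": "young" if row.age < AGE_SPLIT else "old",
                     "correlation": r})
    return pd.DataFrame(rows)


def pseudo_twin_null(matrix: MethylationMatrix, cohort: TwinCohort,
                     n_replicates: int = NULL_REPLICATES, age_split: float = AGE_SPLIT,
                     seed: int = 0, return_draws: bool = False):
    """Age-stratified pseudo-twin null for intra-pair correlation.

    Each replicate draws two distinct true pairs within an age group
    uniformly at random (with replacement across replicates) and correlates
    one randomly chosen member of each.  Returns, per age group, the
    empirical 95% interval ``{"young": (lo, hi), "old": (lo, hi)}`` of the
    pseudo-pair correlations (2.5th and 97.5th percentiles).

    Correlations are computed over probes unmasked in all samples, so the
    null is a single vectorized pass.
    """
    rng = np.random.default_rng(seed)
    prim = cohort.primary
    vals = matrix.masked_values()
    complete = ~vals[prim["sample_id"]].isna().any(axis=1)
    V = vals.loc[complete, prim["sample_id"]].to_numpy(float)
    if V.shape[0] < 3:
        raise ValidationError("fewer than 3 complete probes available for the null")
    # z-score each sample column once; r = z_a . z_b / (P - 1)
    Z = (V - V.mean(axis=0)) / V.std(axis=0, ddof=1)
    n_probes = V.shape[0]

    out = {}
    draws = {}
    ages = prim["age"].to_numpy(float)
    pair_ids = prim["pair_id"].to_numpy()
    for group, sel in (("young", ages < age_split), ("old", ages >= age_split)):
        idx = np.flatnonzero(sel)
        if len(idx) < 4:
            raise ValidationError(f"age group {group!r} has fewer than 4 individuals")
        gpairs = pd.unique(pair_ids[idx])
        if len(gpairs) < 2:
            raise ValidationError(f"age group {group!r} has fewer than 2 pairs")
        members = {p: idx[pair_ids[idx] == p] for p in gpairs}
        # draw two distinct pairs per replicate, then one member of each
        pi = rng.integers(0, len(gpairs), size=n_replicates)
        pj = rng.integers(0, len(gpairs) - 1, size=n_replicates)
        pj = np.where(pj >= pi, pj + 1, pj)  # pj != pi, uniform over the rest
        cols_a = np.array([rng.choice(members[gpairs[i]]) for i in pi])
        cols_b = np.array([rng.choice(members[gpairs[j]]) for j in pj])
        r = np.empty(n_replicates)
        for lo in range(0, n_replicates, 2000):  # chunked to bound memory
            hi = min(lo + 2000, n_replicates)
            r[lo:hi] = np.einsum("ij,ij->j", Z[:, cols_a[lo:hi]], Z[:, cols_b[lo:hi]]) / (n_probes - 1)
        out[group] = (float(np.percentile(r, 2.5)), float(np.percentile(r, 97.5)))
        draws[group] = (pair_ids[cols_a], pair_ids[cols_b])
    if return_draws:
        return out, draws
    return out


def flag_bad_pairs(pair_corrs: pd.DataFrame, null_intervals: dict) -> pd.DataFrame:
    """Flag pairs whose correlation lies strictly below their age group's
    null lower bound.  Returns the input with ``null_lower, null_upper,
    flagged`` columns added."""
    out = pair_corrs.copy()
    out["null_lower"] = out["age_group"].map(lambda g: null_intervals[g][0])
    out["null_upper"] = out["age_group"].map(lambda g: null_intervals[g][1])
    out["flagged"] = out["correlation"] < out["null_lower"]
    out.loc[out["correlation"].isna(), "flagged"] = True  # uncomputable pairs fail QC
    return out


@dataclass
class QCReport:
    """Aggregate QC output: probe SE summary, unstable probes, per-pair
    correlations against the pseudo-twin null, and flagged pairs."""

    probe_se: pd.DataFrame
    unstable_probes: list
    pair_qc: pd.DataFrame
    null_intervals: dict
    se_threshold: float = SE_THRESHOLD

    @property
    def flagged_pairs(self) -> list:
        return list(self.pair_qc.loc[self.pair_qc["flagged"], "pair_id"])

    def to_json(self, path) -> None:
        se = self.probe_se["replicate_se"]
        obj = {
            "se_threshold": self.se_threshold,
            "probe_se_summary": {
                "n_probes": int(se.notna().sum()),
                "median": float(se.median()),
                "q95": float(se.quantile(0.95)),
                "max": float(se.max()),
            },
            "unstable_probes": list(map(str, self.unstable_probes)),
            "null_intervals": {k: list(v) for k, v in self.null_intervals.items()},
            "pair_qc": self.pair_qc.to_dict(orient="records"),
            "flagged_pairs": list(map(str, self.flagged_pairs)),
        }
        Path(path).write_text(json.dumps(obj, indent=1))

    def pair_qc_tsv(self, path) -> None:
        self.pair_qc.to_csv(path, sep="\t", index=False)
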
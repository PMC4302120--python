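"""Core data containers: twin cohorts and methylation matrices.

A :class:`TwinCohort` holds one row per array sample (two per twin pair, plus
optional technical replicates) with the pair-level phenotypes and batch
assignments needed for the paired analysis.  A :class:`MethylationMatrix`
holds a probes x samples value matrix on either the beta scale (methylated
fraction in [0, 1]) or the M-value scale (natural-log odds of methylation),
together with a boolean missingness mask.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["TwinCohort", "MethylationMatrix", "ValidationError"]

COHORT_COLUMNS = [
    "sample_id",
    "pair_id",
    "twin_role",
    "birth_weight",
    "age",
    "sex",
    "birth_year",
    "gestational_age",
    "plate",
    "well",
    "sentrix_position",
    "is_replicate_of",
]

PAIR_CONSTANT = ["age", "sex", "birth_year", "gestational_age", "plate", "well", "sentrix_position"]


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


@dataclass
class TwinCohort:
    """Sample sheet for a monozygotic twin cohort, one row per array sample.

    Rows with a non-null ``is_replicate_of`` are technical replicates of the
    referenced sample and are excluded from pairing invariants and from the
    association analysis; they feed the probe-level replicate QC.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = self.data.reset_index(drop=True)
        self.validate()

    # -- invariants ------------------------------------------------------

    def validate(self) -> None:
        df = self.data
        missing = [c for c in COHORT_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"sample sheet missing columns: {missing}")
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        if len(df) == 0:
            return  # empty cohort: invariants hold vacuously
        prim = self.primary
        if len(prim) == 0:
            raise ValidationError("cohort contains no primary (non-replicate) samples")
        counts = prim.groupby("pair_id").size()
        bad = counts[counts != 2]
        if len(bad):
            raise ValidationError(f"pair ids without exactly two members: {list(bad.index)}")
        roles = prim.groupby("pair_id")["twin_role"].agg(frozenset)
        wrong = roles[roles != frozenset({"bigger", "smaller"})]
        if len(wrong):
            raise ValidationError(f"pairs lacking one bigger and one smaller twin: {list(wrong.index)}")
        for col in PAIR_CONSTANT:
            nun = prim.groupby("pair_id")[col].nunique(dropna=False)
            if (nun > 1).any():
                raise ValidationError(f"column {col!r} not constant within pairs: {list(nun[nun > 1].index)}")
        if (prim["birth_weight"] <= 0).any():
            raise ValidationError("birth weights must be positive")
        piv = prim.pivot(index="pair_id", columns="twin_role", values="birth_weight")
        if (piv["bigger"] < piv["smaller"]).any():
            bad_pairs = piv.index[piv["bigger"] < piv["smaller"]].tolist()
            raise ValidationError(f"bigger twin lighter than smaller twin in pairs: {bad_pairs}")
        reps = df[df["is_replicate_of"].notna()]
        unknown = set(reps["is_replicate_of"]) - set(prim["sample_id"])
        if unknown:
            raise ValidationError(f"replicates reference unknown samples: {sorted(unknown)}")

    # -- views -----------------------------------------------------------

    @property
    def primary(self) -> pd.DataFrame:
        """Non-replicate sample rows."""
        return self.data[self.data["is_replicate_of"].isna()]

    @property
    def replicates(self) -> pd.DataFrame:
        return self.data[self.data["is_replicate_of"].notna()]

    @property
    def n_pairs(self) -> int:
        return self.primary["pair_id"].nunique()

    @property
    def sample_ids(self) -> list:
        return self.data["sample_id"].tolist()

    def pairs(self) -> pd.DataFrame:
        """One row per pair: member sample ids plus the pair-level covariates.

        Columns: ``pair_id, bigger, smaller, bw_bigger, bw_smaller, age, sex,
        birth_year, gestational_age, plate, well, sentrix_position``.
        """
        prim = self.primary
        if len(prim) == 0:
            return pd.DataFrame(columns=["pair_id", "bigger", "smaller", "bw_bigger",
                                         "bw_smaller", *PAIR_CONSTANT])
        piv_id = prim.pivot(index="pair_id", columns="twin_role", values="sample_id")
        piv_bw = prim.pivot(index="pair_id", columns="twin_role", values="birth_weight")
        meta = prim.drop_duplicates("pair_id").set_index("pair_id")[PAIR_CONSTANT]
        out = pd.DataFrame(
            {
                "bigger": piv_id["bigger"],
                "smaller": piv_id["smaller"],
                "bw_bigger": piv_bw["bigger"],
                "bw_smaller": piv_bw["smaller"],
            }
        ).join(meta)
        return out.reset_index()

    def subset_pairs(self, pair_ids) -> "TwinCohort":
        """Restrict to the given pairs (dropping replicates of removed samples)."""
        keep = set(pair_ids)
        df = self.data
        prim_keep = df["is_replicate_of"].isna() & df["pair_id"].isin(keep)
        kept_samples = set(df.loc[prim_keep, "sample_id"])
        rep_keep = df["is_replicate_of"].isin(kept_samples)
        return TwinCohort(df[prim_keep | rep_keep].copy())

    # -- I/O ---------------------------------------------------------------

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TwinCohort":
        df = pd.read_csv(path, dtype={"sample_id": str, "pair_id": str, "is_replicate_of": str,
                                      "plate": str, "well": str, "sentrix_position": str})
        return cls(df)


@dataclass
class MethylationMatrix:
    """Probes x samples methylation values with a missingness mask.

    ``mask`` is True where a value is missing/unreliable.  ``scale`` is
    ``"beta"`` (values in [0, 1] where unmasked) or ``"mvalue"`` (logit of
    beta, natural log).
    """

    values: pd.DataFrame
    scale: str = "beta"
    mask: pd.DataFrame = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = pd.DataFrame(
                np.zeros(self.values.shape, dtype=bool),
                index=self.values.index,
                columns=self.values.columns,
            )
        self.validate()

    def validate(self) -> None:
        if self.scale not in ("beta", "mvalue"):
            raise ValidationError(f"unknown scale {self.scale!r}")
        if self.values.shape != self.mask.shape:
            raise ValidationError(
                f"values {self.values.shape} and mask {self.mask.shape} dimensions disagree"
            )
        if not self.values.index.equals(self.mask.index) or not self.values.columns.equals(self.mask.columns):
            raise ValidationError("values and mask must share probe and sample ids")
        if self.values.index.duplicated().any():
            raise ValidationError("duplicate probe ids")
        if self.values.columns.duplicated().any():
            raise ValidationError("duplicate sample ids")
        if self.scale == "beta":
            vals = self.values.to_numpy()
            unmasked = ~self.mask.to_numpy()
            ok = np.isnan(vals) | (vals >= 0) & (vals <= 1)
            if not ok[unmasked].all():
                raise ValidationError("beta-scale values outside [0, 1]")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self):
        return self.values.shape

    def copy(self) -> "MethylationMatrix":
        return MethylationMatrix(self.values.copy(), self.scale, self.mask.copy())

    def subset_samples(self, sample_ids) -> "MethylationMatrix":
        ids = list(sample_ids)
        return MethylationMatrix(self.values[ids], self.scale, self.mask[ids])

    def subset_probes(self, probe_ids) -> "MethylationMatrix":
        ids = list(probe_ids)
        return MethylationMatrix(self.values.loc[ids], self.scale, self.mask.loc[ids])

    def masked_values(self) -> pd.DataFrame:
        """Values with masked cells replaced by NaN."""
        return self.values.where(~self.mask)

    # -- I/O: TSV dialect (first column probe id, NA = missing) -----------

    def to_tsv(self, path) -> None:
        out = self.masked_values()
        out.index.name = "probe_id"
        out.to_csv(path, sep="\t", na_rep="NA")

    @classmethod
    def from_tsv(cls, path, scale: str = "beta") -> "MethylationMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
        mask = df.isna()
        return cls(df.fillna(0.0 if scale == "beta" else 0.0), scale, mask)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        p, s = self.shape
        return f"MethylationMatrix({p} probes x {s} samples, scale={self.scale!r}, {int(self.mask.to_numpy().sum())} masked)"


def read_matrix_tsv(path, scale: str = "beta") -> MethylationMatrix:
    """Read a probes x samples TSV (optionally gzipped); 'NA' marks missing."""
    return MethylationMatrix.from_tsv(path, scale=scale)
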
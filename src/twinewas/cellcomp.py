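"""Reference-based cell-composition estimation and adjustment.

Whole-blood methylation is a mixture over cell types; composition differences
confound association analyses.  Per sample, proportions of the six canonical
blood cell types (CD8T, CD4T, NK, B cell, monocyte, granulocyte) are
estimated by constrained least squares against a reference profile matrix of
cell-type-specific beta values on discriminating probes: minimize
``||b - R w||^2`` subject to ``w >= 0`` (and optionally ``sum(w) = 1``).
Methylation is then adjusted by regressing each probe's M-values on the
estimated proportions and keeping the residuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize, nnls

from .containers import MethylationMatrix, ValidationError

__all__ = ["CellReference", "estimate_composition", "residualize"]

MIN_PROBE_OVERLAP = 0.8


@dataclass
class CellReference:
    """Reference beta profiles on a discriminating probe subset
    (probes x cell types, values in [0, 1], full column rank)."""

    betas: pd.DataFrame

    def __post_init__(self) -> None:
        b = self.betas.to_numpy(float)
        if b.shape[0] < b.shape[1]:
            raise ValidationError("reference needs at least as many probes as cell types")
        if ((b < 0) | (b > 1)).any():
            raise ValidationError("reference betas must lie in [0, 1]")
        if np.linalg.matrix_rank(b) < b.shape[1]:
            raise ValidationError("reference profile matrix is rank deficient")

    @property
    def probe_ids(self) -> pd.Index:
        return self.betas.index

    @property
    def cell_types(self) -> list:
        return list(self.betas.columns)

    @classmethod
    def from_tsv(cls, path) -> "CellReference":
        return cls(pd.read_csv(path, sep="\t", index_col=0))


def _solve_sum_to_one(R: np.ndarray, b: np.ndarray) -> np.ndarray:
    k = R.shape[1]
    w0, _ = nnls(R, b)
    s = w0.sum()
    x0 = w0 / s if s > 0 else np.full(k, 1.0 / k)
    res = minimize(
        lambda w: float(np.sum((R @ w - b) ** 2)),
        x0,
        jac=lambda w: 2.0 * R.T @ (R @ w - b),
        method="SLSQP",
        bounds=[(0.0, 1.0)] * k,
        constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0,
                      "jac": lambda w: np.ones(k)}],
        options={"ftol": 1e-12, "maxiter": 500},
    )
    return res.x


def estimate_composition(matrix: MethylationMatrix, reference: CellReference,
                         sum_to_one: bool = False) -> pd.DataFrame:
    """Per-sample cell-type proportions by constrained least squares.

    Reference probes absent from the matrix (or masked in a sample) are
    dropped from that sample's fit; at least 80% of reference probes must be
    present overall.  Returns a samples x cell types DataFrame of
    non-negative weights (rows sum to 1 only if ``sum_to_one``).
    """
    if matrix.scale != "beta":
        raise ValidationError("composition estimation expects a beta-scale matrix")
    present = reference.probe_ids.intersection(matrix.probe_ids)
    frac = len(present) / len(reference.probe_ids)
    if frac < MIN_PROBE_OVERLAP:
        raise ValidationError(
            f"only {frac:.0%} of reference probes present in matrix (need >= {MIN_PROBE_OVERLAP:.0%})"
        )
    if frac < 1.0:
        warnings.warn(f"{len(reference.probe_ids) - len(present)} reference probes "
                      "absent from matrix; dropped")
    R_full = reference.betas.loc[present].to_numpy(float)
    sub = matrix.masked_values().loc[present]
    out = np.empty((sub.shape[1], R_full.shape[1]))
    for j, sid in enumerate(sub.columns):
        b = sub[sid].to_numpy(float)
        ok = ~np.isnan(b)
        if ok.sum() < R_full.shape[1]:
            raise ValidationError(f"sample {sid}: too few unmasked reference probes")
        R, bb = R_full[ok], b[ok]
        if sum_to_one:
            out[j] = _solve_sum_to_one(R, bb)
        else:
            out[j], _ = nnls(R, bb)
    return pd.DataFrame(out, index=sub.columns, columns=reference.cell_types)


def residualize(matrix: MethylationMatrix, compositions: pd.DataFrame,
                drop_one: bool = False) -> MethylationMatrix:
    """Remove cell-composition signal: per probe, OLS of M-values on
    intercept + composition columns; the output holds the residuals.

    ``drop_one`` drops the last composition column (needed for
    identifiability when proportions are constrained to sum to one).
    Masked cells are excluded from each fit and stay masked; fits are by
    pseudoinverse, so collinear compositions degrade gracefully to the
    identifiable projection.
    """
    if matrix.scale != "mvalue":
        raise ValidationError("residualize expects an mvalue-scale matrix")
    missing = [s for s in matrix.sample_ids if s not in compositions.index]
    if missing:
        raise ValidationError(f"compositions missing for samples: {missing[:5]}")
    W = compositions.loc[matrix.sample_ids].to_numpy(float)
    if drop_one:
        W = W[:, :-1]
    n, k = W.shape
    if n <= k + 1:
        raise ValidationError(f"need more samples ({n}) than design columns ({k + 1})")
    X = np.column_stack([np.ones(n), W])
    Y = matrix.masked_values().to_numpy(float)  # probes x samples

    resid = np.full_like(Y, np.nan)
    complete = ~np.isnan(Y).any(axis=1)
    if complete.any():
        pinv = np.linalg.pinv(X)
        B = Y[complete] @ pinv.T          # probes x (k+1)
        resid[complete] = Y[complete] - B @ X.T
    for i in np.flatnonzero(~complete):
        ok = ~np.isnan(Y[i])
        if ok.sum() <= k + 1:
            continue  # too few values; leave probe fully masked
        Xi = X[ok]
        Bi = np.linalg.pinv(Xi) @ Y[i, ok]
        resid[i, ok] = Y[i, ok] - Xi @ Bi

    mask = matrix.mask.to_numpy() | np.isnan(resid)
    vals = np.where(np.isnan(resid), 0.0, resid)
    return MethylationMatrix(
        pd.DataFrame(vals, index=matrix.probe_ids, columns=matrix.sample_ids),
        scale="mvalue",
        mask=pd.DataFrame(mask, index=matrix.probe_ids, columns=matrix.sample_ids),
    )
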
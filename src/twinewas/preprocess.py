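"""Intensity-to-beta conversion, detection-p masking, missingness filtering,
and the beta -> M-value (natural-log logit) transform.

Thresholds follow the array-QC conventions of the emulated study: a value
whose detection p exceeds 0.01 (strictly) is treated as missing, and probes
with strictly more than 5% missing values are dropped.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import MethylationMatrix, ValidationError

__all__ = [
    "compute_beta",
    "apply_detection_mask",
    "filter_probes_missingness",
    "to_mvalues",
]

DETECTION_P_THRESHOLD = 0.01
MAX_MISSING_FRAC = 0.05
LOGIT_EPS = 1e-4


def _as_df(x) -> pd.DataFrame:
    return x.values if isinstance(x, MethylationMatrix) else x


def compute_beta(M, U) -> MethylationMatrix:
    """Beta values from methylated/unmethylated intensities: M / (M + U + 100).

    The +100 offset regularizes low-intensity probes; values lie in [0, 1)
    and are never NaN for non-negative intensities.
    """
    M, U = _as_df(M), _as_df(U)
    if M.shape != U.shape:
        raise ValidationError(f"M {M.shape} and U {U.shape} shapes disagree")
    if not (M.index.equals(U.index) and M.columns.equals(U.columns)):
        raise ValidationError("M and U must share probe and sample ids")
    m, u = M.to_numpy(float), U.to_numpy(float)
    if (m < 0).any() or (u < 0).any():
        raise ValidationError("intensities must be non-negative")
    beta = m / (m + u + 100.0)
    return MethylationMatrix(pd.DataFrame(beta, index=M.index, columns=M.columns), scale="beta")


def apply_detection_mask(matrix: MethylationMatrix, detP: pd.DataFrame,
                         threshold: float = DETECTION_P_THRESHOLD) -> MethylationMatrix:
    """Mask cells whose detection p-value strictly exceeds ``threshold``.

    Existing mask entries are preserved; a detection p equal to the
    threshold is kept (strict inequality).
    """
    detP = _as_df(detP)
    if detP.shape != matrix.shape:
        raise ValidationError(f"detection-p {detP.shape} and matrix {matrix.shape} shapes disagree")
    if not (detP.index.equals(matrix.values.index) and detP.columns.equals(matrix.values.columns)):
        raise ValidationError("detection-p matrix must share probe and sample ids")
    new_mask = matrix.mask | (detP > threshold)
    return MethylationMatrix(matrix.values.copy(), matrix.scale, new_mask)


def filter_probes_missingness(matrix: MethylationMatrix,
                              max_missing_frac: float = MAX_MISSING_FRAC):
    """Drop probes whose missing fraction strictly exceeds ``max_missing_frac``.

    Returns ``(filtered_matrix, dropped_probe_ids)``; retained plus dropped
    partition the input probes.
    """
    frac = matrix.mask.to_numpy().mean(axis=1)
    keep = frac <= max_missing_frac
    dropped = matrix.probe_ids[~keep]
    out = MethylationMatrix(matrix.values.loc[keep], matrix.scale, matrix.mask.loc[keep])
    return out, list(dropped)


def to_mvalues(matrix: MethylationMatrix, epsilon: float = LOGIT_EPS) -> MethylationMatrix:
    """Natural-log logit transform: ln(beta / (1 - beta)), beta clipped to
    [epsilon, 1 - epsilon].  Differences of M-values are log odds ratios of
    methylation, so exp(model coefficients) are odds ratios."""
    if matrix.scale != "beta":
        raise ValidationError(f"to_mvalues expects beta scale, got {matrix.scale!r}")
    if not 0 < epsilon < 0.5:
        raise ValidationError("epsilon must be in (0, 0.5)")
    b = np.clip(matrix.values.to_numpy(float), epsilon, 1.0 - epsilon)
    mv = np.log(b / (1.0 - b))
    return MethylationMatrix(
        pd.DataFrame(mv, index=matrix.probe_ids, columns=matrix.sample_ids),
        scale="mvalue",
        mask=matrix.mask.copy(),
    )
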
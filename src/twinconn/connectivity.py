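"""Functional-connectivity matrix construction.

Pearson correlations between all pairs of ROI-mean BOLD time series give an
N x N adjacency matrix per subject.  Non-significant links (two-sided t test,
df = T - 2, alpha = 0.05 by default) are set exactly to zero; the masked
weighted matrix is then optionally binarized at a positive threshold
(default 0.5, strict inequality).
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .io_model import (
    BinaryFCMatrix,
    PValueMatrix,
    ROITimeSeries,
    ValidationError,
    WeightedFCMatrix,
)

__all__ = [
    "compute_fc_matrix",
    "significance_mask",
    "binarize",
    "fc_pipeline",
]


def compute_fc_matrix(ts: ROITimeSeries) -> tuple[WeightedFCMatrix, PValueMatrix]:
    """Pearson FC matrix and two-sided p-values for one subject.

    p(i, j) comes from ``t = r * sqrt((T - 2) / (1 - r^2))`` referred to a t
    distribution on T - 2 degrees of freedom (the standard exact test under
    bivariate normality).  The diagonal is stored as r = 0, p = 1.

    Raises
    ------
    ValidationError
        If any ROI column is constant (its correlation is undefined).
    """
    x = ts.values
    t_len, _ = x.shape
    sd = x.std(axis=0)
    if np.any(sd == 0.0):
        bad = [ts.parcellation.labels[i] for i in np.flatnonzero(sd == 0.0)]
        raise ValidationError(
            f"subject {ts.subject_id}: constant time series for ROIs {bad}"
        )
    r = np.corrcoef(x, rowvar=False)
    np.fill_diagonal(r, 0.0)
    # guard against r = +/-1 from numerically identical columns
    df = t_len - 2
    r_clip = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        tstat = r_clip * np.sqrt(df / np.maximum(1.0 - r_clip**2, 0.0))
    p = 2.0 * stats.t.sf(np.abs(tstat), df)
    np.fill_diagonal(p, 1.0)
    p = np.minimum(p, 1.0)
    p = (p + p.T) / 2.0  # enforce exact symmetry against rounding noise
    r = (r_clip + r_clip.T) / 2.0
    return (
        WeightedFCMatrix(r, ts.parcellation),
        PValueMatrix(p, ts.parcellation),
    )


def significance_mask(
    weighted: WeightedFCMatrix, pvalues: PValueMatrix, alpha: float = 0.05
) -> WeightedFCMatrix:
    """Zero out links with p >= alpha; keep significant links unchanged.

    Both positive and negative significant correlations are retained, so the
    signed-strength node metrics remain meaningful downstream.
    """
    if not (0.0 < alpha < 1.0):
        raise ValidationError(f"alpha must lie strictly in (0, 1), got {alpha}")
    if weighted.parcellation != pvalues.parcellation:
        raise ValidationError("weighted and p-value matrices use different parcellations")
    masked = np.where(pvalues.values < alpha, weighted.values, 0.0)
    np.fill_diagonal(masked, 0.0)
    return WeightedFCMatrix(masked, weighted.parcellation)


def binarize(weighted: WeightedFCMatrix, tau: float = 0.5) -> BinaryFCMatrix:
    """Binarize at a positive threshold: edge iff weight > tau (strict).

    Negative weights never produce edges.  The threshold is defined as
    positive, so tau <= 0 is rejected.
    """
    if tau <= 0.0:
        raise ValidationError(f"binarization threshold must be positive, got {tau}")
    return BinaryFCMatrix(
        (weighted.values > tau).astype(float), weighted.parcellation
    )


def fc_pipeline(
    ts: ROITimeSeries, alpha: float = 0.05, tau: float = 0.5
) -> tuple[WeightedFCMatrix, BinaryFCMatrix]:
    """Time series -> significance-masked weighted FC and binarized FC."""
    unmasked, pvals = compute_fc_matrix(ts)
    masked = significance_mask(unmasked, pvals, alpha=alpha)
    return masked, binarize(masked, tau=tau)
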
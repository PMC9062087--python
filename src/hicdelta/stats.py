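"""Small shared statistics helpers."""

from __future__ import annotations

import numpy as np
from scipy.stats import chi2 as chi2_dist

__all__ = ["pearson_chi2"]


def pearson_chi2(table) -> tuple[float, int, float]:
    """Pearson chi-square for an r x c count table, no continuity correction.

    Returns (statistic, dof, p).  Degenerate tables (a zero row or column
    margin) carry no evidence of association and return statistic 0, p 1.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or (t < 0).any():
        raise ValueError("table must be a 2-D array of non-negative counts")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    total = t.sum()
    dof = (t.shape[0] - 1) * (t.shape[1] - 1)
    if total == 0 or (rows == 0).any() or (cols == 0).any():
        return 0.0, dof, 1.0
    expected = np.outer(rows, cols) / total
    stat = float(((t - expected) ** 2 / expected).sum())
    p = float(chi2_dist.sf(stat, dof))
    return stat, dof, p
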
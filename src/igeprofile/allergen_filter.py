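"""Mann-Whitney filtering of asthma-relevant allergens.

Allergens whose class-score distributions differ between asthmatic and
non-asthmatic subjects (two-sided Mann-Whitney U, p < α, default α=0.05)
are retained; the filtered panel is then used to rebuild profiles for
re-clustering and for classifier training. The threshold is applied to
raw p-values — Benjamini-Hochberg q-values are reported as an extra
column for transparency but play no part in retention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import ReactivityMatrix

#: exact enumeration is feasible and preferable below this combined size
EXACT_MAX_N = 20


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test between two score groups.

    Returns (U of the first group, two-sided p). p is computed by exact
    enumeration when n₁+n₂ ≤ 20 and the data are tie-free, otherwise by
    the normal approximation with tie-corrected variance and continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
        # all observations identical: no evidence either way
        return x.size * y.size / 2.0, 1.0
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    small = x.size + y.size <= EXACT_MAX_N
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


@dataclass
class FilterResult:
    table: pd.DataFrame  # allergen_id, U, p, q_bh, retained
    alpha: float

    @property
    def retained_allergens(self) -> list[str]:
        return self.table.loc[self.table["retained"], "allergen_id"].tolist()

    @property
    def n_retained(self) -> int:
        return int(self.table["retained"].sum())


def filter_allergens(
    matrix: ReactivityMatrix,
    asthma_status: np.ndarray,
    alpha: float = 0.05,
) -> FilterResult:
    """One Mann-Whitney test per allergen column, affected vs not affected.

    ``asthma_status`` is a boolean array over the matrix rows (True =
    asthmatic); subjects with undefined diagnosis must be excluded from
    the matrix before calling. Constant columns get p = 1 and are never
    retained.
    """
    status = np.asarray(asthma_status, dtype=bool)
    if status.size != matrix.n_subjects:
        raise ValueError("status labels do not cover matrix rows")
    if status.all() or (~status).all():
        raise ValueError("both asthmatic and non-asthmatic subjects required")
    rows = []
    for j, allergen in enumerate(matrix.allergen_ids):
        col = matrix.values[:, j]
        if np.all(col == col[0]):
            u, p = status.sum() * (~status).sum() / 2.0, 1.0
        else:
            u, p = mann_whitney_u(col[status], col[~status])
        rows.append((allergen, u, p))
    table = pd.DataFrame(rows, columns=["allergen_id", "U", "p"])
    table["q_bh"] = multipletests(table["p"], method="fdr_bh")[1]
    table["retained"] = table["p"] < alpha
    return FilterResult(table, alpha)
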
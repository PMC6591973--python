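"""Expression-matrix handling: tissue filtering, clustering, 2^-dCt and t-tests.

The matrix is a genes x tissues pandas DataFrame of non-negative intensities
(eFP-browser-style values); missing values stay NaN and are excluded from
statistics.  Tissue codes follow the compendium convention: ML mature leaf,
YL young leaf, RT root, FC female catkin, MC male catkin, XY developing
xylem.
"""

from __future__ import annotations

import math
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import ttest_ind

__all__ = [
    "TISSUES",
    "load_expression_tsv",
    "select_high_tissue",
    "log2_heatmap_cluster",
    "ddct_expression",
    "two_sample_test",
]

TISSUES = ["ML", "YL", "RT", "FC", "MC", "XY"]


def load_expression_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df < 0).any().any():
        raise ValueError("expression matrix contains negative values")
    return df


def select_high_tissue(
    matrix: pd.DataFrame,
    tissue: str,
    threshold: float = 1000.0,
    pairs: Optional[Iterable[tuple[str, str]]] = None,
) -> set[str]:
    """Genes with tissue value strictly above `threshold`, closed under
    duplication-pair partnership ("corresponding replication genes")."""
    if tissue not in matrix.columns:
        raise KeyError(f"unknown tissue {tissue!r}")
    selected = set(matrix.index[matrix[tissue] > threshold])
    if pairs:
        pair_list = [tuple(p) for p in pairs]
        changed = True
        while changed:
            changed = False
            for a, b in pair_list:
                if a in selected and b not in selected and b in matrix.index:
                    selected.add(b)
                    changed = True
                if b in selected and a not in selected and a in matrix.index:
                    selected.add(a)
                    changed = True
    return selected


def log2_heatmap_cluster(
    matrix: pd.DataFrame, linkage: str = "average", metric: str = "euclidean"
) -> tuple[list[str], np.ndarray, pd.DataFrame]:
    """log2(x+1) transform and hierarchical row clustering.

    Returns (leaf order as gene ids, scipy linkage matrix, transformed
    matrix).  The leaf order is deterministic: scipy's tie-break keeps lower
    original indices first.
    """
    if len(matrix) < 2:
        raise ValueError("clustering needs at least 2 genes")
    values = np.log2(matrix.to_numpy(dtype=float) + 1.0)
    Z = hierarchy.linkage(values, method=linkage, metric=metric)
    order = hierarchy.leaves_list(Z)
    transformed = pd.DataFrame(values, index=matrix.index, columns=matrix.columns)
    return [matrix.index[i] for i in order], Z, transformed


def ddct_expression(ct_target: float, ct_ref: float) -> float:
    """Relative qPCR expression by the comparative Ct method: 2^-(Ct_t - Ct_ref)."""
    if not (math.isfinite(ct_target) and math.isfinite(ct_ref)):
        raise ValueError("Ct values must be finite")
    return 2.0 ** -(ct_target - ct_ref)


def two_sample_test(
    group_a: Iterable[float], group_b: Iterable[float], equal_var: bool = True
) -> tuple[float, str]:
    """Two-sided two-sample t-test (pooled variance by default) with
    significance stars: p < 0.01 -> '**', p < 0.05 -> '*'."""
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 replicate values per group")
    if a.std() == 0 and b.std() == 0:
        p = 1.0 if a.mean() == b.mean() else 0.0
    else:
        p = float(ttest_ind(a, b, equal_var=equal_var).pvalue)
    if p < 0.01:
        stars = "**"
    elif p < 0.05:
        stars = "*"
    else:
        stars = ""
    return p, stars
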
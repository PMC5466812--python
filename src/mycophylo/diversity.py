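"""Alpha diversity (Hill numbers, Chao 1), Bray-Curtis beta diversity, and
paired DNA-vs-RNA comparisons.

Hill numbers give the effective number of equally abundant OTUs at order
q: q=0 is richness, q=1 the exponential of Shannon entropy, q=2 the
inverse Simpson concentration. A community is unambiguously more diverse
than another only if its whole Hill profile lies above.

Bray-Curtis dissimilarities can be computed either on raw counts or with
the transformation conventional in community ordination: square root of
the counts followed by Wisconsin double standardization (each OTU scaled
by its maximum across samples, then each sample by its total).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import braycurtis
from skbio.diversity.alpha import chao1 as _skbio_chao1

__all__ = [
    "hill_number",
    "hill_profile",
    "chao1",
    "wisconsin",
    "bray_curtis_matrix",
    "compare_paired",
    "alpha_diversity_table",
]

DEFAULT_Q_GRID = tuple(np.arange(0, 3.25, 0.25))


def hill_number(counts, q: float) -> float:
    """Effective number of OTUs of order q >= 0.

    ``(sum p_i^q)^(1/(1-q))`` over the positive proportions, with the
    q=1 Shannon limit ``exp(-sum p_i ln p_i)`` and 0*log(0) = 0.
    """
    if q < 0:
        raise ValueError("Hill order q must be >= 0")
    x = np.asarray(counts, dtype=float)
    if (x < 0).any():
        raise ValueError("negative counts")
    total = x.sum()
    if total == 0:
        raise ValueError("all-zero community")
    p = x[x > 0] / total
    if q == 0:
        return float(p.size)
    if abs(q - 1.0) < 1e-9:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(np.sum(p**q) ** (1.0 / (1.0 - q)))


def hill_profile(counts, q_grid=DEFAULT_Q_GRID) -> pd.Series:
    """Hill numbers over a grid of orders (non-increasing in q)."""
    return pd.Series({q: hill_number(counts, q) for q in q_grid}, name="hill")


def chao1(counts) -> float:
    """Bias-corrected Chao 1 richness estimate.

    ``S_obs + F1(F1-1) / (2(F2+1))`` with F1 singletons and F2
    doubletons; finite even when no doubletons are observed, and never
    below the observed richness. Undefined for non-integer counts.
    """
    x = np.asarray(counts, dtype=float)
    if not np.allclose(x, np.round(x)):
        raise ValueError("Chao 1 requires integer counts")
    if (x < 0).any():
        raise ValueError("negative counts")
    return float(_skbio_chao1(x.astype(np.int64), bias_corrected=True))


def wisconsin(matrix: pd.DataFrame) -> pd.DataFrame:
    """Wisconsin double standardization of an OTU x sample matrix.

    Rows (OTUs) are divided by their maximum across samples, then each
    sample column by its total.
    """
    m = matrix.div(matrix.max(axis=1).replace(0, np.nan), axis=0).fillna(0.0)
    return m.div(m.sum(axis=0), axis=1)


def bray_curtis_matrix(matrix: pd.DataFrame, transform: str = "wisconsin_sqrt") -> pd.DataFrame:
    """Symmetric Bray-Curtis dissimilarity matrix over sample columns.

    ``transform='wisconsin_sqrt'`` applies the ordination convention (square
    root, then Wisconsin double standardization) before computing
    BC(x, y) = sum|x_i - y_i| / sum(x_i + y_i); ``'none'`` uses the raw
    columns.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need >= 2 columns")
    if (matrix.sum(axis=0) == 0).any():
        zero = list(matrix.columns[matrix.sum(axis=0) == 0])
        raise ValueError(f"all-zero columns: {zero}")
    if transform == "wisconsin_sqrt":
        work = wisconsin(np.sqrt(matrix))
    elif transform == "none":
        work = matrix.astype(float)
    else:
        raise ValueError(f"unknown transform {transform!r}")
    cols = list(matrix.columns)
    n = len(cols)
    d = np.zeros((n, n))
    arr = work.to_numpy()
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = braycurtis(arr[:, i], arr[:, j])
    return pd.DataFrame(d, index=cols, columns=cols)


def compare_paired(a, b, method: str = "paired_t") -> dict:
    """Two-sided paired comparison of per-sample values.

    ``paired_t`` is Student's t on the differences; ``wilcoxon_signed_rank``
    drops zero differences and uses the exact null for n <= 25, the
    tie-corrected normal approximation above. Degenerate input (all
    differences zero) is reported as p = 1 with ``degenerate=True``
    rather than an error.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired vectors must be 1-d and equal length")
    if x.size < 3:
        raise ValueError("need >= 3 pairs")
    diffs = x - y
    if np.allclose(diffs, 0):
        return {"statistic": np.nan, "p_value": 1.0, "degenerate": True}
    if method == "paired_t":
        if np.isclose(np.std(diffs, ddof=1), 0.0):
            # constant nonzero difference: t is unbounded
            return {"statistic": np.inf * np.sign(diffs[0]), "p_value": 0.0,
                    "degenerate": False}
        res = stats.ttest_rel(x, y)
    elif method == "wilcoxon_signed_rank":
        nz = diffs[diffs != 0]
        mode = "exact" if nz.size <= 25 and not _has_ties(nz) else "approx"
        res = stats.wilcoxon(x, y, zero_method="wilcox", mode=mode)
    else:
        raise ValueError(f"unknown method {method!r}")
    return {"statistic": float(res.statistic), "p_value": float(res.pvalue),
            "degenerate": False}


def _has_ties(diffs: np.ndarray) -> bool:
    mags = np.abs(diffs)
    return np.unique(mags).size < mags.size


def alpha_diversity_table(table, q_grid=DEFAULT_Q_GRID) -> pd.DataFrame:
    """Per (sample, fraction) Hill profile and Chao 1, one row per column."""
    rows = {}
    for col in table.counts.columns:
        counts = table.counts[col].to_numpy()
        prof = {f"hill_q{q:g}": hill_number(counts, q) for q in q_grid}
        prof["chao1"] = chao1(counts)
        rows[col] = prof
    out = pd.DataFrame(rows).T
    out.index = pd.MultiIndex.from_tuples(out.index, names=["sample", "fraction"])
    return out
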
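"""Phylogenetic signal: Blomberg's K, its measurement-error variant Kse,
and a permutation test on the variance of independent contrasts.

Blomberg's K compares how the observed trait variance partitions on the
tree against the Brownian-motion expectation:

    K = (MSE0 / MSE)_obs / (MSE0 / MSE)_BM

with a_hat = (1'C^-1 x) / (1'C^-1 1) the phylogenetic GLS mean,
MSE0 = (x - a_hat)'(x - a_hat) / (n - 1),
MSE  = (x - a_hat)' C^-1 (x - a_hat) / (n - 1), and BM expectation
(tr C - n / 1'C^-1 1) / (n - 1). K = 1 matches Brownian motion, K < 1
means relatives are less similar than BM predicts (e.g. divergent
expression among close relatives), K > 1 more similar.

Kse accounts for per-tip measurement error (here, the SE of each OTU's
mean expression ratio over samples): the trait is modelled as
x ~ N(a 1, sigma2 C + diag(se^2)); sigma2 is estimated by maximum
likelihood and K is evaluated with C replaced by
C* = sigma2_hat C + diag(se^2). With all SEs zero this reduces exactly
to K (K is invariant to the overall scale of C).

Significance is assessed non-parametrically: the statistic is the mean
squared standardized independent contrast, whose null distribution is
obtained by shuffling trait labels across the tips; strong signal gives
anomalously low contrast variance, so the test is lower-tailed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg, optimize

from . import phylo

__all__ = ["KResult", "blomberg_k", "kse", "k_significance", "signal_table"]


@dataclass(frozen=True)
class KResult:
    scope: str
    k: float
    used_se: bool
    p_value: float
    n_permutations: int
    n_tips: int
    degenerate: bool = False


def _prune_to(tree: dendropy.Tree, labels) -> dendropy.Tree:
    """Subtree spanned by the given tip labels (clone; suppresses unifurcations)."""
    keep = set(labels)
    tips = set(phylo.tip_labels(tree))
    missing = keep - tips
    if missing:
        raise KeyError(f"tips not in tree: {sorted(missing)}")
    if keep == tips:
        return tree
    work = tree.clone(depth=1)
    work.retain_taxa_with_labels(sorted(keep))
    return work


def _chol_solve(c: np.ndarray, b: np.ndarray, jitter_events: list | None = None):
    """Solve C z = b via Cholesky, with logged jitter on failure."""
    try:
        cf = linalg.cho_factor(c, lower=True)
    except linalg.LinAlgError:
        eps = 1e-10 * np.trace(c) / c.shape[0]
        if jitter_events is not None:
            jitter_events.append(eps)
        warnings.warn(f"VCV Cholesky failed; adding jitter {eps:.3e}")
        cf = linalg.cho_factor(c + eps * np.eye(c.shape[0]), lower=True)
    return linalg.cho_solve(cf, b)


def _k_from_vcv(c: np.ndarray, x: np.ndarray) -> float:
    """K with an explicit (possibly error-inflated) covariance structure."""
    n = len(x)
    ones = np.ones(n)
    cinv_one = _chol_solve(c, ones)
    cinv_x = _chol_solve(c, x)
    denom_one = ones @ cinv_one
    a_hat = (ones @ cinv_x) / denom_one
    resid = x - a_hat
    mse0 = resid @ resid / (n - 1)
    mse = resid @ _chol_solve(c, resid) / (n - 1)
    if mse <= 0 or mse0 <= 0:
        raise ValueError("degenerate (constant) trait: K undefined")
    expected = (np.trace(c) - n / denom_one) / (n - 1)
    return float((mse0 / mse) / expected)


def _aligned(tree: dendropy.Tree, trait: pd.Series):
    sub = _prune_to(tree, trait.index)
    order = phylo.tip_labels(sub)
    x = trait.reindex(order).to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite trait values")
    return sub, order, x


def blomberg_k(tree: dendropy.Tree, trait: pd.Series) -> float:
    """Blomberg's K of a tip trait.

    The trait index may cover a subset of the tips, in which case the
    tree is pruned to it; at least 4 tips are required.
    """
    sub, order, x = _aligned(tree, trait)
    if len(order) < 4:
        raise ValueError("K requires >= 4 tips")
    c = phylo.vcv_matrix(sub).loc[order, order].to_numpy()
    return _k_from_vcv(c, x)


def kse(
    tree: dendropy.Tree,
    trait: pd.Series,
    se: pd.Series,
    return_details: bool = False,
):
    """K with per-tip measurement error (the SE of each trait mean).

    Fits sigma2 by ML under x ~ N(a 1, sigma2 C + diag(se^2)) and
    evaluates K on C* = sigma2_hat C + diag(se^2). Reduces to
    :func:`blomberg_k` when every SE is zero. Raises on non-finite SEs;
    flags the result degenerate when the ML rate collapses to ~0
    (signal unidentifiable, e.g. SEs vastly exceeding trait spread).
    """
    sub, order, x = _aligned(tree, trait)
    if len(order) < 4:
        raise ValueError("K requires >= 4 tips")
    s = se.reindex(order).to_numpy(dtype=float)
    if not np.all(np.isfinite(s)) or (s < 0).any():
        raise ValueError("SEs must be finite and non-negative")
    c = phylo.vcv_matrix(sub).loc[order, order].to_numpy()
    d2 = s**2
    if np.allclose(d2, 0.0):
        k = _k_from_vcv(c, x)
        return (k, {"sigma2": np.nan, "degenerate": False}) if return_details else k

    n = len(x)
    ones = np.ones(n)

    def negloglik(log_sig2: float) -> float:
        v = np.exp(log_sig2) * c + np.diag(d2)
        try:
            cf = linalg.cho_factor(v, lower=True)
        except linalg.LinAlgError:
            return 1e12
        logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
        vi_one = linalg.cho_solve(cf, ones)
        vi_x = linalg.cho_solve(cf, x)
        a = (ones @ vi_x) / (ones @ vi_one)
        r = x - a
        vi_r = linalg.cho_solve(cf, r)
        return 0.5 * (r @ vi_r + logdet + n * np.log(2 * np.pi))

    # bracket sigma2 around the naive contrast-variance scale
    scale = max(np.var(x) / max(np.trace(c) / n, 1e-12), 1e-12)
    res = optimize.minimize_scalar(
        negloglik,
        bounds=(np.log(scale) - 18.0, np.log(scale) + 18.0),
        method="bounded",
        options={"xatol": 1e-8},
    )
    if not res.success:
        raise RuntimeError(f"Kse ML optimisation failed: {res.message}")
    sig2 = float(np.exp(res.x))
    # unidentifiable when the fitted phylogenetic variance is a negligible
    # share of the total (measurement error dominates every tip)
    phylo_share = sig2 * np.trace(c) / (sig2 * np.trace(c) + d2.sum())
    degenerate = phylo_share < 1e-6 or res.x <= np.log(scale) - 17.5
    k = _k_from_vcv(sig2 * c + np.diag(d2), x)
    if return_details:
        return k, {"sigma2": sig2, "degenerate": degenerate}
    return k


def k_significance(
    tree: dendropy.Tree,
    trait: pd.Series,
    n_permutations: int = 999,
    seed: int = 0,
) -> float:
    """Permutation p-value for phylogenetic signal.

    Statistic: mean squared standardized independent contrast. Null:
    trait values shuffled across the tips. Lower tail — true signal
    concentrates trait change on long branches, shrinking contrasts —
    with the add-one rule p = (count(null <= obs) + 1)/(n_perm + 1).
    """
    if n_permutations < 99:
        raise ValueError("use at least 99 permutations")
    sub, order, x = _aligned(tree, trait)
    w, w_order = phylo.contrast_operator(sub)
    x = trait.reindex(w_order).to_numpy(dtype=float)
    observed = np.mean((w @ x) ** 2)
    rng = np.random.default_rng(seed)
    n = len(x)
    perms = np.empty((n, n_permutations))
    for j in range(n_permutations):
        perms[:, j] = x[rng.permutation(n)]
    null = np.mean((w @ perms) ** 2, axis=0)
    return float((np.sum(null <= observed) + 1) / (n_permutations + 1))


def signal_table(
    scoped_trees: dict[str, dendropy.Tree],
    trait_table: pd.DataFrame,
    n_permutations: int = 999,
    seed: int = 0,
    exclude_tips: set[str] | None = None,
) -> pd.DataFrame:
    """Kse and significance per scope (whole tree and/or per phylum).

    ``trait_table`` is the mean-expression-ratio output (columns
    ``value``, ``se``). For each named tree, tips are restricted to
    OTUs with trait values (reference taxa in ``exclude_tips`` are
    removed first); scopes with < 4 usable tips are skipped with a
    warning. Stars follow the usual thresholds (* <0.05, ** <0.01,
    *** <0.001).
    """
    exclude = exclude_tips or set()
    seeds = np.random.SeedSequence(seed).generate_state(len(scoped_trees)) >> 1
    rows = []
    for i, (scope, tree) in enumerate(scoped_trees.items()):
        tips = [
            t for t in phylo.tip_labels(tree)
            if t in trait_table.index and t not in exclude
        ]
        if len(tips) < 4:
            warnings.warn(f"scope {scope!r} has {len(tips)} usable tips; skipped")
            continue
        trait = trait_table.loc[tips, "value"]
        se = trait_table.loc[tips, "se"]
        k, details = kse(tree, trait, se, return_details=True)
        p = k_significance(tree, trait, n_permutations, int(seeds[i]))
        rows.append(
            {
                "scope": scope,
                "kse": k,
                "p_value": p,
                "stars": _stars(p),
                "n_tips": len(tips),
                "n_permutations": n_permutations,
                "degenerate": details["degenerate"],
            }
        )
    return pd.DataFrame(rows)


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"
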
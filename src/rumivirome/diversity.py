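"""Beta-diversity, permutation tests, and differential-abundance filtering.

PERMANOVA is implemented here (adonis2-style one-factor sum-of-squares
partition of the distance matrix) because restricted permutations within
strata — needed when a blocking factor such as breed confounds the grouping —
are part of the contract. Bray-Curtis distances, ordination and multiple-
testing correction ride on scipy, scikit-bio and statsmodels.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa
from statsmodels.stats.multitest import multipletests

from .types import AbundanceTable

__all__ = [
    "bray_curtis",
    "pcoa",
    "permanova",
    "diff_abundance",
    "bh_adjust",
    "kruskal_wallis",
]


def bray_curtis(table: AbundanceTable) -> pd.DataFrame:
    """Sample x sample Bray-Curtis dissimilarity: sum|x-y| / sum(x+y)."""
    X = table.values.to_numpy(dtype=float)
    zero = table.values.sum(axis=1) == 0
    if zero.any():
        bad = table.values.index[zero][0]
        raise ValueError(f"sample {bad!r} has all-zero counts")
    D = squareform(pdist(X, metric="braycurtis"))
    return pd.DataFrame(D, index=table.values.index, columns=table.values.index)


def pcoa(dist: pd.DataFrame) -> dict:
    """Classical scaling (PCoA) of a distance matrix.

    Axes with negative eigenvalues are dropped; their total magnitude is
    reported instead of being corrected away. Returns a dict with
    ``coordinates`` (samples x axes), ``eigenvalues`` (positive axes only),
    ``proportion_explained`` and ``negative_eigenvalue_magnitude``.
    """
    D = np.asarray(dist, dtype=float)
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix is not symmetric")
    ids = list(dist.index) if isinstance(dist, pd.DataFrame) else None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = _skbio_pcoa(DistanceMatrix(D, ids=ids), method="eigh")
    eigvals = res.eigvals.to_numpy()
    keep = eigvals > 1e-12
    coords = res.samples.iloc[:, keep]
    pos = eigvals[keep]
    return {
        "coordinates": coords,
        "eigenvalues": pos,
        "proportion_explained": pos / pos.sum() if pos.sum() > 0 else pos,
        "negative_eigenvalue_magnitude": float(-eigvals[eigvals < 0].sum()),
    }


def _permanova_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    n = len(codes)
    ss_total = d2.sum() / (2 * n)
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        ss_within += d2[np.ix_(idx, idx)].sum() / (2 * len(idx))
    ss_among = ss_total - ss_within
    return (ss_among / (n_groups - 1)) / (ss_within / (n - n_groups))


def permanova(
    dist: pd.DataFrame,
    groups,
    n_perm: int = 999,
    strata=None,
    seed: int = 0,
) -> dict:
    """One-factor PERMANOVA with optional restricted permutations.

    With ``strata`` given, permutations shuffle group labels only within each
    block, the appropriate null when the blocking factor (e.g. breed)
    confounds the grouping. ``p = (1 + #{F_perm >= F_obs}) / (1 + n_perm)``.
    """
    D = np.asarray(dist, dtype=float)
    d2 = D**2
    labels = np.asarray(groups)
    names, codes = np.unique(labels, return_inverse=True)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    n = len(codes)
    n_groups = len(names)

    f_obs = _permanova_f(d2, codes, n_groups)
    ss_total = d2.sum() / (2 * n)
    ss_w = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        ss_w += d2[np.ix_(idx, idx)].sum() / (2 * len(idx))
    r2 = (ss_total - ss_w) / ss_total

    rng = np.random.default_rng(seed)
    if strata is not None:
        strata = np.asarray(strata)
        block_idx = [np.flatnonzero(strata == b) for b in np.unique(strata)]
        for idx in block_idx:
            if len(np.unique(codes[idx])) == 1:
                warnings.warn(
                    "a stratum lies entirely in one group: no permutation possible within it"
                )

    count = 0
    for _ in range(n_perm):
        perm = codes.copy()
        if strata is None:
            rng.shuffle(perm)
        else:
            for idx in block_idx:
                perm[idx] = perm[idx[rng.permutation(len(idx))]]
        if _permanova_f(d2, perm, n_groups) >= f_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return {"pseudo_F": float(f_obs), "R2": float(r2), "p": float(p), "n_perm": n_perm}


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone in p-rank, q <= 1)."""
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def kruskal_wallis(values, groups, exact_max_n: int = 10) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction.

    p comes from the chi-square approximation (df = k-1); for total n <=
    ``exact_max_n`` the exact permutation distribution is fully enumerated
    instead.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(groups)
    names = np.unique(labels)
    group_vals = [values[labels == g] for g in names]
    if len(values) == 0 or any(len(g) == 0 for g in group_vals):
        raise ValueError("every group must be non-empty")
    if all((values == values[0])):
        return 0.0, 1.0
    h_obs, p_chi2 = stats.kruskal(*group_vals)

    n = len(values)
    if n > exact_max_n:
        return float(h_obs), float(p_chi2)

    # exact enumeration over all distinct assignments of observations to groups
    sizes = [len(g) for g in group_vals]
    idx_all = list(range(n))
    count = total = 0

    def _h(assignment: list[np.ndarray]) -> float:
        groups_v = [values[a] for a in assignment]
        flat = np.concatenate(groups_v)
        if (flat == flat[0]).all():
            return 0.0
        return stats.kruskal(*groups_v)[0]

    def _recurse(remaining: list[int], gi: int, chosen: list[np.ndarray]):
        nonlocal count, total
        if gi == len(sizes) - 1:
            assignment = chosen + [np.array(remaining, dtype=int)]
            total += 1
            if _h(assignment) >= h_obs - 1e-12:
                count += 1
            return
        for comb in itertools.combinations(remaining, sizes[gi]):
            rest = [i for i in remaining if i not in comb]
            _recurse(rest, gi + 1, chosen + [np.array(comb, dtype=int)])

    _recurse(idx_all, 0, [])
    return float(h_obs), count / total


def diff_abundance(
    table: AbundanceTable,
    groups,
    abund_min: float = 1e-4,
    prev_min: float = 0.6,
    votu_prev_min: float = 0.5,
    q_max: float = 0.1,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Differential abundance with the study's pre-test filters.

    Microbial features (count tables) must exceed ``abund_min`` relative
    abundance in at least ``prev_min`` of samples; coverage tables (vOTUs)
    must be non-zero in at least ``votu_prev_min`` of samples. Retained
    features are tested with a linear model on CLR-transformed values (an
    uncorrected CLR model standing in for bias-corrected compositional
    regression) and BH-adjusted; ``significant`` marks q < ``q_max``.
    The effect is the CLR mean difference (second group minus first, in
    sorted group order) for two-group designs.
    """
    from .networks import clr_transform

    labels = np.asarray(groups)
    names = np.unique(labels)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")

    X = table.values
    if table.value_kind in ("read_count", "relative_abundance"):
        rel = table.relative().values
        kept_mask = (rel > abund_min).mean(axis=0) >= prev_min
    else:
        kept_mask = (X > 0).mean(axis=0) >= votu_prev_min
    kept_cols = X.columns[kept_mask]

    out = pd.DataFrame(
        {"feature": X.columns, "kept": kept_mask.to_numpy()}
    ).set_index("feature")
    out["effect"] = np.nan
    out["p"] = np.nan

    if len(kept_cols) > 0:
        clr = clr_transform(X.to_numpy(dtype=float), pseudocount)
        clr = pd.DataFrame(clr, index=X.index, columns=X.columns)[kept_cols]
        masks = [labels == g for g in names]
        for feat in kept_cols:
            vals = clr[feat].to_numpy()
            parts = [vals[m] for m in masks]
            if len(names) == 2:
                t, p = stats.ttest_ind(parts[1], parts[0], equal_var=True)
                effect = parts[1].mean() - parts[0].mean()
            else:
                _, p = stats.f_oneway(*parts)
                effect = np.nan
            if np.isnan(p):  # zero variance in both groups
                p, effect = 1.0, 0.0
            out.loc[feat, ["effect", "p"]] = effect, p
        out.loc[kept_cols, "q"] = bh_adjust(out.loc[kept_cols, "p"].to_numpy())
    else:
        out["q"] = np.nan
    out["significant"] = out["q"] < q_max
    return out
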
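"""Community profiling: prevalence, core taxa, accumulation curves, and
viral-richness proxies."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .core import PRESENCE_THRESHOLD, call_taxon_presence
from .types import AbundanceTable

__all__ = [
    "prevalence",
    "core_taxa",
    "genus_rollup",
    "accumulation_curve",
    "viral_richness_proxy",
    "richness_correlation",
]


def prevalence(
    table: AbundanceTable, presence_threshold: float = PRESENCE_THRESHOLD
) -> pd.Series:
    """Fraction of samples in which each taxon is present."""
    if len(table.values.index) == 0:
        raise ValueError("empty table")
    present = call_taxon_presence(table, presence_threshold)
    return present.mean(axis=0)


def core_taxa(
    table: AbundanceTable, presence_threshold: float = PRESENCE_THRESHOLD
) -> set[str]:
    """Taxa present in 100% of samples (strict: absent in one sample excludes)."""
    prev = prevalence(table, presence_threshold)
    return set(prev.index[prev == 1.0])


def genus_rollup(table: AbundanceTable) -> AbundanceTable:
    """Genus-level table obtained by summing species counts sharing the genus rank."""
    if not table.taxa:
        raise ValueError("genus rollup needs TaxonRecord annotations")
    genus_of = {t.taxon_id: (t.genus or t.taxon_id) for t in table.taxa}
    grouped = table.values.T.groupby(
        [genus_of.get(c, c) for c in table.values.columns]
    ).sum().T
    return AbundanceTable(grouped, table.value_kind, table.samples)


def accumulation_curve(
    table: AbundanceTable,
    start_n: int = 100,
    step: int = 5,
    n_repeats: int = 100,
    seed: int = 0,
    presence_threshold: float = PRESENCE_THRESHOLD,
) -> pd.DataFrame:
    """Core-taxon counts under incremental sample accumulation.

    Each repeat shuffles the samples, starts from ``start_n`` of them and adds
    ``step`` at a time (without replacement), recording the running core count
    at every size. Returns a repeat x size DataFrame of core counts; within
    any repeat the count is monotone non-increasing.
    """
    n = len(table.values.index)
    if start_n > n:
        raise ValueError(f"start_n={start_n} exceeds the {n} available samples")
    rng = np.random.default_rng(seed)
    present = call_taxon_presence(table, presence_threshold).to_numpy()
    sizes = list(range(start_n, n + 1, step))
    if sizes[-1] != n:
        sizes.append(n)
    rows = np.empty((n_repeats, len(sizes)), dtype=np.int64)
    for r in range(n_repeats):
        order = rng.permutation(n)
        # running intersection of present-sets in shuffled order
        cum = np.cumprod(present[order], axis=0, dtype=bool)
        rows[r] = [int(cum[k - 1].sum()) for k in sizes]
    return pd.DataFrame(rows, columns=sizes)


def viral_richness_proxy(mapped_viral_reads: int, total_bases: int) -> float:
    """Reads mapped to the viral database per Gb of metagenomic sequence."""
    if total_bases <= 0:
        raise ValueError("total_bases must be positive")
    if mapped_viral_reads < 0:
        raise ValueError("mapped_viral_reads must be non-negative")
    return mapped_viral_reads / (total_bases / 1e9)


def richness_correlation(viral, microbial) -> tuple[float, float]:
    """Spearman correlation between paired viral and microbial richness values.

    Returns (rho, p); (nan, nan) with a warning when either vector is
    constant (zero rank variance).
    """
    viral = np.asarray(viral, dtype=float)
    microbial = np.asarray(microbial, dtype=float)
    if viral.shape != microbial.shape:
        raise ValueError("viral and microbial vectors differ in length")
    if len(viral) < 4:
        raise ValueError("need at least 4 paired observations")
    if np.ptp(viral) == 0 or np.ptp(microbial) == 0:
        warnings.warn("constant input: Spearman correlation undefined")
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(viral, microbial)
    return float(rho), float(p)
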
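"""Coverage summaries and presence calls shared by all downstream stages."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import AbundanceTable, CoverageProfile

__all__ = [
    "trimmed_mean_coverage",
    "breadth",
    "call_taxon_presence",
    "PRESENCE_THRESHOLD",
]

#: Default presence cutoff: a taxon must exceed 0.001% of assigned reads.
PRESENCE_THRESHOLD = 1e-5


def trimmed_mean_coverage(profile: CoverageProfile, trim_frac: float = 0.05) -> float:
    """Mean per-position depth after discarding the lowest and highest ``trim_frac``
    quantiles of positions (CoverM-style trimmed mean, default 5% per side).
    """
    if not 0 <= trim_frac < 0.5:
        raise ValueError(f"trim_frac must be in [0, 0.5), got {trim_frac}")
    n = profile.length
    if n == 0:
        raise ValueError(f"{profile.seq_id}: empty sequence")
    k = int(np.floor(trim_frac * n))
    ordered = np.sort(profile.depths)
    return float(ordered[k : n - k].mean())


def breadth(profile: CoverageProfile, min_depth: int = 1) -> float:
    """Fraction of positions covered at depth >= ``min_depth``."""
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    if profile.length == 0:
        raise ValueError(f"{profile.seq_id}: empty sequence")
    return float(np.count_nonzero(profile.depths >= min_depth)) / profile.length


def call_taxon_presence(
    table: AbundanceTable, threshold: float = PRESENCE_THRESHOLD
) -> pd.DataFrame:
    """Boolean sample x taxon presence matrix.

    A taxon is present in a sample iff its relative abundance (proportion of
    the sample's classified reads) strictly exceeds ``threshold``. The default
    1e-5 corresponds to the >0.001%-of-assigned-reads rule.
    """
    if not 0 <= threshold < 1:
        raise ValueError(f"threshold must be in [0, 1), got {threshold}")
    if table.value_kind not in ("read_count", "relative_abundance"):
        raise ValueError("presence calls need read counts or relative abundances")
    rel = table.relative().values
    return rel > threshold
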
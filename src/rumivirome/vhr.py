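"""Virus-to-host ratio (VHR) computation and grouped comparison.

VHR is the trimmed-mean coverage of a prophage genome divided by the number
of reads assigned to its predicted host species — deliberately mixed units,
used as a within-linkage proxy for prophage induction/replication state.
Host read counts enter raw (unnormalized); the group comparison is
rank-based within each linkage, which makes it insensitive to the scale.
"""

from __future__ import annotations

import math
import warnings

import pandas as pd

from .diversity import bh_adjust, kruskal_wallis
from .types import VHRRecord

__all__ = ["compute_vhr", "compare_vhr_groups"]


def compute_vhr(prophage_cov: float, host_reads: int) -> float:
    """prophage coverage / host reads; NaN (never infinity) when no host reads."""
    if prophage_cov < 0 or host_reads < 0:
        raise ValueError("negative inputs")
    if host_reads == 0:
        return float("nan")
    return prophage_cov / host_reads


def compare_vhr_groups(
    records: list[VHRRecord],
    min_group_n: int = 6,
    q_max: float = 0.01,
) -> pd.DataFrame:
    """Per-linkage Kruskal-Wallis comparison of VHR across groups.

    Groups represented by fewer than ``min_group_n`` samples are dropped
    before testing; linkages left with fewer than two groups are excluded
    and reported with NaN statistics. p-values are BH-adjusted across the
    tested linkages; ``significant`` marks q < ``q_max`` (default 0.01).
    """
    df = pd.DataFrame(
        {
            "linkage": [f"{r.votu_id}|{r.host_taxon}" for r in records],
            "group": [r.group for r in records],
            "vhr": [r.vhr for r in records],
        }
    ).dropna(subset=["vhr"])

    rows = []
    for linkage, sub in df.groupby("linkage", sort=True):
        sizes = sub.groupby("group").size()
        kept = sizes.index[sizes >= min_group_n]
        sub = sub[sub["group"].isin(kept)]
        n_groups = sub["group"].nunique()
        if n_groups < 2:
            rows.append(
                {"linkage": linkage, "H": math.nan, "p": math.nan, "n_groups": n_groups,
                 "n_samples": len(sub), "tested": False}
            )
            continue
        h, p = kruskal_wallis(
            sub["vhr"].to_numpy(), sub["group"].to_numpy(), exact_max_n=12
        )
        rows.append(
            {"linkage": linkage, "H": float(h), "p": float(p), "n_groups": n_groups,
             "n_samples": len(sub), "tested": True}
        )

    out = pd.DataFrame(rows)
    if out.empty or not out["tested"].any():
        warnings.warn("no linkage passed the group-size filter")
        out["q"] = math.nan
        out["significant"] = False
        return out
    tested = out["tested"]
    out.loc[tested, "q"] = bh_adjust(out.loc[tested, "p"].to_numpy())
    out["significant"] = out["q"] < q_max
    return out
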
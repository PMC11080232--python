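"""Prophage calling, vOTU clustering, activity classification, and ARG screening.

Viral discovery itself (VirSorter2/CheckV/VIBRANT-style) is consumed as
annotation input; what is implemented here is the two-category prophage rule
(integrated-provirus flags plus lysogeny marker genes), fragment-based ANI
clustering into vOTUs, coverage-ratio activity calls, and the strict
identity/coverage ARG filter.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from Bio import Align

from .core import breadth
from .types import ContigAnnotation, CoverageProfile, ProphageRegion, VOTURecord

__all__ = [
    "DEFAULT_MARKERS",
    "call_prophages",
    "pairwise_ani",
    "cluster_votus",
    "classify_activity",
    "classify_activity_any",
    "screen_args",
]

#: Lysogeny marker genes: integrase, excisionase (x2), Cro repressor, CI repressor.
DEFAULT_MARKERS = frozenset({"VOG00021", "VOG00006", "VOG05065", "VOG00002", "VOG00692"})


def call_prophages(
    annotations: list[ContigAnnotation],
    marker_set: frozenset[str] = DEFAULT_MARKERS,
) -> list[ProphageRegion]:
    """Apply the two-category prophage rule to annotated contigs.

    A contig with an integrated-provirus flag yields one ``checkv_integrated``
    region at the flagged interval; a contig with no flag but at least one
    lysogeny marker gene yields one whole-contig ``marker_gene`` region (the
    interval is recorded but approximate: the rule cannot localize the
    prophage within the contig). Host MAG and species are inherited from the
    contig's source MAG.
    """
    regions: list[ProphageRegion] = []
    for ann in annotations:
        if ann.provirus_flag:
            if ann.provirus_region is None:
                raise ValueError(f"{ann.seq_id}: provirus_flag set without an interval")
            start, end = ann.provirus_region
            if not (0 <= start < end <= ann.length):
                raise ValueError(
                    f"{ann.seq_id}: provirus interval [{start},{end}) outside contig bounds"
                )
            regions.append(
                ProphageRegion(
                    prophage_id=f"{ann.seq_id}_pp0",
                    host_mag=ann.source_mag,
                    host_species=ann.host_species,
                    seq_id=ann.seq_id,
                    start=start,
                    end=end,
                    category="checkv_integrated",
                )
            )
            continue
        markers = frozenset().union(
            *(vogs & marker_set for _, _, _, vogs in ann.genes)
        ) if ann.genes else frozenset()
        if markers:
            regions.append(
                ProphageRegion(
                    prophage_id=f"{ann.seq_id}_pp0",
                    host_mag=ann.source_mag,
                    host_species=ann.host_species,
                    seq_id=ann.seq_id,
                    start=0,
                    end=ann.length,
                    category="marker_gene",
                    markers_found=markers,
                )
            )
    return regions


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    return aligner


def pairwise_ani(
    a: str,
    b: str,
    fragment_len: int = 500,
    min_fragment: int = 100,
    min_align_frac: float = 0.5,
) -> tuple[float, float]:
    """Fragment-based ANI between two sequences.

    The shorter sequence is cut into ``fragment_len`` pieces, each locally
    aligned (match +1 / mismatch -1 / gap -2) to the longer. A fragment counts
    as aligning when the local alignment spans at least ``min_align_frac`` of
    it. Returns ``(ani, aligned_frac_of_shorter)``: mean identity over
    aligning fragments and aligned fragment bases over the shorter length.
    Symmetric by construction.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    aligner = _make_aligner()

    identities: list[float] = []
    aligned_bases = 0
    for start in range(0, len(short), fragment_len):
        frag = short[start : start + fragment_len]
        if len(frag) < min_fragment:
            continue
        alignments = aligner.align(long_, frag)
        if len(alignments) == 0 or alignments.score <= 0:
            continue
        aln = alignments[0]
        frag_start, frag_end = aln.aligned[1][0][0], aln.aligned[1][-1][-1]
        span = frag_end - frag_start
        if span < min_align_frac * len(frag):
            continue
        counts = aln.counts()
        columns = counts.identities + counts.mismatches + counts.gaps
        if columns == 0:
            continue
        identities.append(counts.identities / columns)
        aligned_bases += span

    ani = float(np.mean(identities)) if identities else 0.0
    return ani, aligned_bases / len(short)


def cluster_votus(
    sequences: dict[str, str],
    ani_threshold: float = 0.95,
    cov_threshold: float = 0.85,
    fragment_len: int = 500,
) -> list[VOTURecord]:
    """Greedy centroid clustering into vOTUs at >=95% ANI over >=85% of the
    shorter sequence.

    Sequences are visited longest-first (ties by lexicographic id), so every
    representative is the longest member of its cluster and the output is
    invariant to input presentation order.
    """
    if not sequences:
        raise ValueError("no sequences to cluster")
    order = sorted(sequences, key=lambda s: (-len(sequences[s]), s))
    reps: list[str] = []
    members: dict[str, list[str]] = {}
    for seq_id in order:
        placed = False
        for rep in reps:
            ani, cov = pairwise_ani(sequences[seq_id], sequences[rep], fragment_len)
            if ani >= ani_threshold and cov >= cov_threshold:
                members[rep].append(seq_id)
                placed = True
                break
        if not placed:
            reps.append(seq_id)
            members[seq_id] = [seq_id]
    return [
        VOTURecord(
            votu_id=f"vOTU{k:04d}",
            representative=rep,
            members=frozenset(members[rep]),
            rep_length=len(sequences[rep]),
        )
        for k, rep in enumerate(reps)
    ]


def classify_activity(
    region: ProphageRegion,
    prophage_cov: CoverageProfile,
    flank_cov: CoverageProfile,
    min_ratio: float = 1.65,
    min_effect: float = 0.6,
) -> str:
    """Classify a prophage as active, cryptic, or untested in one sample.

    Active requires both an elevated median depth ratio (prophage over
    flanking host, >= ``min_ratio``) and a Cohen's d effect size >=
    ``min_effect`` between the two depth vectors. The call is ``untested``
    when either profile has breadth (depth >= 1) below 0.5 or the flank is
    shorter than 1 kb. Defaults mirror PropagAtE-style thresholds.
    """
    if flank_cov.length < 1000 or prophage_cov.length == 0:
        return "untested"
    if breadth(prophage_cov, 1) < 0.5 or breadth(flank_cov, 1) < 0.5:
        return "untested"
    med_p = float(np.median(prophage_cov.depths))
    med_f = float(np.median(flank_cov.depths))
    ratio = np.inf if med_f == 0 else med_p / med_f
    pooled = np.sqrt((prophage_cov.depths.var(ddof=1) + flank_cov.depths.var(ddof=1)) / 2)
    d = 0.0 if pooled == 0 else (prophage_cov.depths.mean() - flank_cov.depths.mean()) / pooled
    return "active" if (ratio >= min_ratio and d >= min_effect) else "cryptic"


def classify_activity_any(
    region: ProphageRegion,
    per_sample: list[tuple[CoverageProfile, CoverageProfile]],
    min_ratio: float = 1.65,
    min_effect: float = 0.6,
) -> str:
    """OR-fold over samples: non-cryptic (active) if active in any sample;
    cryptic if tested somewhere and never active; untested otherwise."""
    calls = [
        classify_activity(region, p, f, min_ratio, min_effect) for p, f in per_sample
    ]
    if "active" in calls:
        return "active"
    if "cryptic" in calls:
        return "cryptic"
    return "untested"


def screen_args(
    hits: pd.DataFrame, id_min: float = 80.0, cov_min: float = 40.0
) -> pd.DataFrame:
    """Retain ARG hits at strictly greater than ``id_min``% identity and
    ``cov_min``% subject coverage, excluding mutation-conferred resistance.

    Expects columns ``pct_identity``, ``subject_coverage`` (0-100 scale) and
    ``mutation_conferred`` (boolean).
    """
    for col in ("pct_identity", "subject_coverage"):
        vals = hits[col].to_numpy(dtype=float)
        if np.isnan(vals).any() or (vals < 0).any() or (vals > 100).any():
            raise ValueError(f"malformed percentage in column {col}")
    keep = (
        (hits["pct_identity"] > id_min)
        & (hits["subject_coverage"] > cov_min)
        & (~hits["mutation_conferred"].astype(bool))
    )
    return hits.loc[keep].copy()
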
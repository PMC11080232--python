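"""CRISPR array detection, protospacer matching, and strain-level host linkage.

The detector is a CRT/MinCED-style exact-repeat scanner: short k-mer seeds
recurring at admissible spacings are extended to maximal repeats and chained
into arrays, with a tandem-repeat guard on spacer similarity. Spacers of at
least 30 bp are matched full-length and ungapped against both strands of the
viral genomes; only perfect (zero-mismatch) hits qualify for host linkage,
while single-mismatch hits are reported separately as candidate escape
mutations in the virus-host arms race.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd

from .core import breadth
from .types import CoverageProfile, CrisprArray, GenomeRecord, HostLinkage, SpacerMatch

__all__ = [
    "detect_crispr_arrays",
    "extract_spacers",
    "match_protospacers",
    "strain_present",
    "votu_present",
    "link_hosts",
    "classify_specificity",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _spacer_identity(a: str, b: str) -> float:
    """Ungapped offset-0 identity, penalizing length difference."""
    matches = sum(1 for x, y in zip(a, b) if x == y)
    return matches / max(len(a), len(b))


def detect_crispr_arrays(
    seq_id: str,
    seq: str,
    min_repeats: int = 3,
    repeat_len: tuple[int, int] = (23, 47),
    spacer_len: tuple[int, int] = (26, 50),
    k: int = 8,
    max_spacer_identity: float = 0.6,
) -> list[CrisprArray]:
    """Scan one contig (forward orientation) for repeat-spacer arrays.

    Exact ``k``-mer seeds recurring at a spacing compatible with one
    repeat+spacer period are extended to maximal exact repeats within the
    length bounds, then chained into runs of >= ``min_repeats`` repeats whose
    gaps (spacers) fall in ``spacer_len``. Arrays whose spacers are mutually
    more than ``max_spacer_identity`` identical are rejected as tandem
    repeats. Returns an empty list when nothing qualifies.
    """
    seq = seq.upper()
    n = len(seq)
    if n < 100:
        return []
    min_period = repeat_len[0] + spacer_len[0]
    max_period = repeat_len[1] + spacer_len[1]

    positions: dict[str, list[int]] = {}
    for i in range(n - k + 1):
        positions.setdefault(seq[i : i + k], []).append(i)

    # Chain seed occurrences at admissible periods into candidate runs, then
    # fix repeat boundaries by consensus across ALL copies: extension stops at
    # the first position where any copy disagrees, so a chance boundary match
    # between just two copies cannot shift the repeat.
    candidates: list[tuple[int, ...]] = []
    seen_runs: set[tuple[int, ...]] = set()
    for pos_list in positions.values():
        if len(pos_list) < min_repeats:
            continue
        run = [pos_list[0]]
        for pos in pos_list[1:] + [n + max_period + 1]:  # sentinel flushes last run
            if min_period <= pos - run[-1] <= max_period:
                run.append(pos)
            else:
                if len(run) >= min_repeats and tuple(run) not in seen_runs:
                    seen_runs.add(tuple(run))
                    candidates.append(tuple(run))
                run = [pos]

    arrays: list[CrisprArray] = []
    seen_spans: list[tuple[int, int]] = []
    # longest runs first so a full array claims its span before sub-runs do
    for run in sorted(candidates, key=lambda r: (-len(r), r[0])):
        gaps = [run[i + 1] - run[i] for i in range(len(run) - 1)]
        left = 0
        while (
            run[0] - left - 1 >= 0
            and k + left < repeat_len[1]
            and min(gaps) - (k + left) > spacer_len[0]
            and len({seq[p - left - 1] for p in run}) == 1
        ):
            left += 1
        right = 0
        while (
            run[-1] + k + right < n
            and k + left + right < repeat_len[1]
            and min(gaps) - (k + left + right) > spacer_len[0]
            and len({seq[p + k + right] for p in run}) == 1
        ):
            right += 1
        length = k + left + right
        if length < repeat_len[0]:
            continue
        starts = [p - left for p in run]
        repeat = seq[starts[0] : starts[0] + length]
        spacer_gaps = [starts[i + 1] - (starts[i] + length) for i in range(len(starts) - 1)]
        if any(not spacer_len[0] <= g <= spacer_len[1] for g in spacer_gaps):
            continue
        span = (starts[0], starts[-1] + length)
        if any(not (span[1] <= s or span[0] >= e) for s, e in seen_spans):
            continue  # nested/overlapping re-detection of the same locus
        spacers = [
            (starts[i] + length, starts[i + 1], seq[starts[i] + length : starts[i + 1]])
            for i in range(len(starts) - 1)
        ]
        pair_idents = [
            _spacer_identity(s1[2], s2[2])
            for i, s1 in enumerate(spacers)
            for s2 in spacers[i + 1 :]
        ]
        if pair_idents and float(np.mean(pair_idents)) > max_spacer_identity:
            continue  # tandem-repeat guard
        seen_spans.append(span)
        arrays.append(
            CrisprArray(
                array_id=f"{seq_id}_crispr{len(arrays)}",
                seq_id=seq_id,
                repeats=[(p, p + length, repeat) for p in starts],
                spacers=spacers,
                consensus_repeat=repeat,
            )
        )
    arrays.sort(key=lambda arr: arr.repeats[0][0])
    for i, arr in enumerate(arrays):
        arr.array_id = f"{seq_id}_crispr{i}"
    return arrays


def extract_spacers(arrays: list[CrisprArray], min_len: int = 30) -> dict[str, str]:
    """Spacers of at least ``min_len`` bp (inclusive), keyed ``array_id:ordinal``."""
    out: dict[str, str] = {}
    for arr in arrays:
        for ordinal, (_, _, spacer) in enumerate(arr.spacers):
            if len(spacer) >= min_len:
                out[f"{arr.array_id}:{ordinal}"] = spacer
    return out


def _seq_to_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def match_protospacers(
    spacers: Mapping[str, str],
    votu_seqs: Mapping[str, str],
    max_mismatches: int = 1,
) -> list[SpacerMatch]:
    """Full-length ungapped spacer matches on both strands of each vOTU.

    Every occurrence with at most ``max_mismatches`` mismatches is reported;
    positions are 0-based on the vOTU forward strand (a ``-`` hit means the
    reverse complement of the spacer occurs there). Zero-mismatch hits
    qualify for linkage; single-mismatch hits are arms-race candidates.
    """
    for sid, sp in spacers.items():
        if set(sp.upper()) - set("ACGT"):
            raise ValueError(f"spacer {sid} contains non-ACGT symbols")

    hits: list[SpacerMatch] = []
    for votu_id, target in votu_seqs.items():
        t = _seq_to_array(target.upper())
        for sid, sp in spacers.items():
            sp = sp.upper()
            L = len(sp)
            if L > len(t):
                continue
            windows = np.lib.stride_tricks.sliding_window_view(t, L)
            for strand, probe in (("+", sp), ("-", reverse_complement(sp))):
                mm = (windows != _seq_to_array(probe)).sum(axis=1)
                for pos in np.flatnonzero(mm <= max_mismatches):
                    hits.append(
                        SpacerMatch(
                            spacer_id=sid,
                            votu_id=votu_id,
                            position=int(pos),
                            strand=strand,
                            mismatches=int(mm[pos]),
                        )
                    )
    return hits


def strain_present(
    mag: GenomeRecord,
    cov: Mapping[str, CoverageProfile],
    min_reads: int = 5,
    min_breadth: float = 0.5,
    total_reads: int | None = None,
    read_len: int = 150,
) -> bool:
    """Strain presence: >= ``min_reads`` reads mapped AND aggregate coverage
    breadth >= ``min_breadth`` across the MAG's scaffolds (both gates must
    hold). When the mapped-read count is not given it is estimated from the
    depth tracks as total covered bases / ``read_len``.
    """
    profiles = [cov[c] for c in mag.contig_ids if c in cov]
    if not profiles:
        warnings.warn(f"MAG {mag.mag_id}: no coverage record; treated as absent")
        return False
    covered = sum(int(np.count_nonzero(p.depths >= 1)) for p in profiles)
    total_len = mag.total_length
    agg_breadth = covered / total_len if total_len else 0.0
    if total_reads is None:
        total_reads = int(sum(float(p.depths.sum()) for p in profiles) / read_len)
    return total_reads >= min_reads and agg_breadth >= min_breadth


def votu_present(
    votu_id: str, cov: CoverageProfile, min_covered_frac: float = 0.7
) -> bool:
    """vOTU presence: coverage breadth (depth >= 1) of at least ``min_covered_frac``."""
    if cov.length == 0:
        return False
    return breadth(cov, 1) >= min_covered_frac


def link_hosts(
    matches: list[SpacerMatch],
    mag_of_array: Mapping[str, str],
    presence: pd.DataFrame,
) -> list[HostLinkage]:
    """Strain-level host linkages from zero-mismatch spacer matches plus
    same-sample co-occurrence.

    ``presence`` is a boolean sample x entity DataFrame whose columns include
    both MAG ids and vOTU ids. A linkage exists iff at least one perfect
    spacer match connects the pair AND at least one sample contains both;
    ``supporting_samples`` lists every such sample.
    """
    pair_spacers: dict[tuple[str, str], set[str]] = {}
    for m in matches:
        if m.mismatches != 0:
            continue
        array_id = m.spacer_id.rsplit(":", 1)[0]
        mag_id = mag_of_array[array_id]
        pair_spacers.setdefault((mag_id, m.votu_id), set()).add(m.spacer_id)

    linkages: list[HostLinkage] = []
    for (mag_id, votu_id), spacer_ids in sorted(pair_spacers.items()):
        if mag_id not in presence.columns or votu_id not in presence.columns:
            continue
        both = presence[mag_id] & presence[votu_id]
        samples = frozenset(presence.index[both])
        if samples:
            linkages.append(HostLinkage(mag_id, votu_id, samples, frozenset(spacer_ids)))
    return linkages


def classify_specificity(
    linkages: list[HostLinkage],
    presence: pd.DataFrame,
    strain_catalog: list[GenomeRecord],
) -> pd.DataFrame:
    """Per-sample host-specificity fractions of linked vOTUs.

    In each sample every present vOTU linked to >= 1 present MAG is classed:
    ``multi_species`` when its present linked MAGs span two or more species;
    ``conspecific_partial`` when they are a strict subset of the present
    strains of a single species (co-existing conspecific strains lack a
    matching spacer); ``single_strain`` otherwise. Fractions are over the
    sample's classified (linked) vOTUs and sum to 1.
    """
    species_of = {g.mag_id: g.species for g in strain_catalog}
    strains_of_species: dict[str, set[str]] = {}
    for g in strain_catalog:
        strains_of_species.setdefault(g.species, set()).add(g.mag_id)

    votu_mags: dict[str, set[str]] = {}
    for lk in linkages:
        votu_mags.setdefault(lk.votu_id, set()).add(lk.mag_id)

    rows = []
    for sample in presence.index:
        present = set(presence.columns[presence.loc[sample]])
        counts = {"single_strain": 0, "multi_species": 0, "conspecific_partial": 0}
        for votu_id, mags in sorted(votu_mags.items()):
            if votu_id in presence.columns and votu_id not in present:
                continue  # vOTU not observed in this sample
            linked_present = {m for m in mags if m in present}
            if not linked_present:
                continue  # excluded from the denominator
            species = {species_of[m] for m in linked_present}
            if len(species) >= 2:
                counts["multi_species"] += 1
            else:
                (sp,) = species
                present_conspecifics = strains_of_species[sp] & present
                if linked_present < present_conspecifics:
                    counts["conspecific_partial"] += 1
                else:
                    counts["single_strain"] += 1
        n = sum(counts.values())
        if n == 0:
            continue
        rows.append(
            {
                "sample_id": sample,
                "n_votus": n,
                **{cls: cnt / n for cls, cnt in counts.items()},
            }
        )
    return pd.DataFrame(rows).set_index("sample_id") if rows else pd.DataFrame(
        columns=["n_votus", "single_strain", "multi_species", "conspecific_partial"]
    )
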
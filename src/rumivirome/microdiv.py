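"""Gene-level micro-diversity: pN/pS with coverage gating, prophage-carriage
calls, and positive-selection flags.

pN/pS compares the observed density of nonsynonymous and synonymous SNVs
within a read population. Opportunity counting follows Nei-Gojobori: each
codon position contributes fractional synonymous/nonsynonymous "sites"
according to the fates of its three possible point mutations, with
stop-producing changes counted as nonsynonymous.
"""

from __future__ import annotations

import math
import warnings

from Bio.Data import CodonTable

from .core import breadth
from .types import CoverageProfile, GeneModel, GenomeRecord, SNVCall

__all__ = [
    "CODON_TO_AA",
    "STOP_CODONS",
    "codon_site_counts",
    "classify_snv",
    "gene_pnps",
    "strain_carries_prophage",
    "flag_positive_selection",
]

_standard = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_standard.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_standard.stop_codons)


def codon_site_counts(codon: str) -> tuple[float, float]:
    """(synonymous sites, nonsynonymous sites) for one sense codon.

    Over the 9 possible single-base changes, ``syn = 3 * fraction
    synonymous``; the two always sum to exactly 3. Stop-producing changes
    count as nonsynonymous.
    """
    codon = codon.upper()
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon} has no site counts")
    if codon not in CODON_TO_AA:
        raise ValueError(f"not a valid codon: {codon!r}")
    aa = CODON_TO_AA[codon]
    syn = 0
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            mutated = codon[:pos] + base + codon[pos + 1 :]
            if mutated not in STOP_CODONS and CODON_TO_AA[mutated] == aa:
                syn += 1
    syn_sites = syn / 3.0
    return syn_sites, 3.0 - syn_sites


def classify_snv(gene: GeneModel, snv: SNVCall) -> str:
    """Classify one SNV as 'syn' or 'nonsyn' against the reference codon."""
    if not gene.start <= snv.position < gene.end:
        raise ValueError(f"SNV at {snv.position} outside gene {gene.gene_id}")
    rel = snv.position - gene.start
    ci = rel // 3
    codon = gene.codons[3 * ci : 3 * ci + 3].upper()
    within = rel % 3
    if codon[within] != snv.ref.upper():
        raise ValueError(
            f"SNV ref {snv.ref} does not match gene {gene.gene_id} at offset {rel}"
        )
    mutated = codon[:within] + snv.alt.upper() + codon[within + 1 :]
    if codon in STOP_CODONS:
        raise ValueError(f"gene {gene.gene_id}: reference codon is a stop")
    if mutated in STOP_CODONS:
        return "nonsyn"
    return "syn" if CODON_TO_AA[mutated] == CODON_TO_AA[codon] else "nonsyn"


def gene_pnps(
    gene: GeneModel,
    snvs: list[SNVCall],
    cov: CoverageProfile,
    min_breadth: float = 0.99,
    min_depth: float = 10.0,
    mode: str = "site_normalized",
) -> float | None:
    """pN/pS of one gene in one sample, or None when gates fail.

    Gates: the gene's coverage breadth (depth >= 1) must exceed ``min_breadth``
    and its mean depth must reach ``min_depth`` (defaults: >99% and 10x).
    ``site_normalized`` divides observed counts by Nei-Gojobori site counts;
    ``raw_counts`` is the bare Nobs/Sobs ratio. Returns ``math.inf`` when
    Sobs = 0 with Nobs > 0, and None when there are no SNVs at all.

    Multi-allelic positions contribute each alternate allele as a separate
    substitution event.
    """
    if mode not in ("site_normalized", "raw_counts"):
        raise ValueError(f"unknown mode {mode!r}")
    if cov.length == 0 or breadth(cov, 1) <= min_breadth:
        return None
    if float(cov.depths.mean()) < min_depth:
        return None

    n_obs = s_obs = 0
    for snv in snvs:
        kind = classify_snv(gene, snv)
        if kind == "syn":
            s_obs += 1
        else:
            n_obs += 1
    if n_obs == 0 and s_obs == 0:
        return None

    if mode == "raw_counts":
        return math.inf if s_obs == 0 else n_obs / s_obs

    s_sites = n_sites = 0.0
    for ci in range(len(gene.codons) // 3):
        s, n = codon_site_counts(gene.codons[3 * ci : 3 * ci + 3])
        s_sites += s
        n_sites += n
    pn = n_obs / n_sites
    ps = s_obs / s_sites
    return math.inf if ps == 0 else pn / ps


def strain_carries_prophage(
    mag: GenomeRecord,
    cov_by_scaffold: dict[str, CoverageProfile],
    min_breadth: float = 0.99,
) -> bool:
    """True iff every scaffold of the MAG (prophage scaffolds included) has
    coverage breadth strictly above ``min_breadth`` (default >99%).
    """
    for seq_id in mag.contig_ids:
        prof = cov_by_scaffold.get(seq_id)
        if prof is None:
            warnings.warn(f"MAG {mag.mag_id}: no coverage for scaffold {seq_id}")
            return False
        if prof.length == 0 or breadth(prof, 1) <= min_breadth:
            return False
    return True


def flag_positive_selection(pnps_by_sample: dict[str, float | None]) -> dict:
    """Flag a gene as under diversifying selection when pN/pS > 1 in a strict
    majority of the samples where it passed the coverage gates.
    """
    passing = {s: v for s, v in pnps_by_sample.items() if v is not None}
    n_pass = len(passing)
    n_above = sum(1 for v in passing.values() if v > 1)
    if n_pass == 0:
        return {"flagged": False, "status": "untested", "n_passing": 0, "n_above_one": 0}
    return {
        "flagged": n_above > n_pass / 2,
        "status": "tested",
        "n_passing": n_pass,
        "n_above_one": n_above,
    }
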
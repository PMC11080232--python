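"""Synthetic rumen community generator.

Emits multi-strain species with integrated prophages, CRISPR arrays whose
spacers derive from co-occurring viral genomes, log-normal sample abundances
with group effects, Poisson per-position coverage, and codon-level SNVs under
tunable selection — together with truth tables for every planted feature, so
downstream recall/precision can be scored without re-derivation.

All generators are pure functions of (config, seed): the same seed yields
byte-identical output. Host genome background is i.i.d. uniform nucleotides,
which minimizes accidental repeats that would confound the CRISPR detector's
false-positive tests. Prophage insertion models no attachment-site
duplication, and the standard genetic code (NCBI table 1) drives SNV
simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .microdiv import CODON_TO_AA, STOP_CODONS
from .types import (
    AbundanceTable,
    CoverageProfile,
    CrisprArray,
    GenomeRecord,
    ProphageRegion,
    SampleMeta,
    SNVCall,
)

__all__ = [
    "SimConfig",
    "CommunitySim",
    "simulate_community",
    "simulate_abundances",
    "simulate_coverage",
    "simulate_snvs",
    "simulate_network_abundances",
    "precision_truth_edges",
    "chain_precision",
    "coupled_virus_host_precision",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")

#: Minimum host sequence flanking a planted prophage on each side (bp).
MIN_FLANK = 5000


@dataclass
class SimConfig:
    """Knobs of the synthetic community.

    Defaults mirror the structure of the real study system at desk scale:
    about half of the strains carry a prophage, most strains carry a CRISPR
    array, and most spacers are copied verbatim from a co-occurring viral
    genome.
    """

    seed: int
    n_species: int = 6
    strains_per_species: tuple[int, int] = (1, 3)  # inclusive range
    genome_len: tuple[int, int] = (40_000, 60_000)
    n_votus: int = 10
    votu_len: tuple[int, int] = (8_000, 15_000)
    prophage_rate: float = 0.5
    crispr_rate: float = 0.7
    spacer_source_frac: float = 0.7
    n_samples: int = 20
    abundance_lognormal_sigma: float = 1.0
    group_effects: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    depth_mean: float = 20.0
    omega: float = 1.0
    vhr_induction_factor: float = 1.0
    induced_group: str | None = None
    strain_divergence: float = 0.005  # substitutions/bp between conspecific strains

    def __post_init__(self) -> None:
        for name in ("prophage_rate", "crispr_rate", "spacer_source_frac"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.vhr_induction_factor <= 0:
            raise ValueError("vhr_induction_factor must be positive")


@dataclass
class CommunitySim:
    """Output bundle of :func:`simulate_community` (sequences plus truth tables)."""

    genomes: list[GenomeRecord]
    genome_seqs: dict[str, str]  # contig seq_id -> sequence
    votus: dict[str, str]  # votu_id -> sequence
    prophage_truth: list[ProphageRegion]
    crispr_truth: list[CrisprArray]
    linkage_truth: set[tuple[str, str]]  # (mag_id, votu_id)

    @property
    def species_ids(self) -> list[str]:
        return sorted({g.species for g in self.genomes})


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute each base independently with probability ``rate``."""
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = rng.random(len(arr)) < rate
    idx = np.flatnonzero(hit)
    for i in idx:
        choices = [b for b in _BASES if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return arr.tobytes().decode()


def simulate_community(cfg: SimConfig) -> CommunitySim:
    """Build genomes, viral genomes, and planted prophage/CRISPR/linkage truth."""
    rng = np.random.default_rng(cfg.seed)

    votus = {
        f"vOTU{i:03d}": _random_seq(rng, int(rng.integers(cfg.votu_len[0], cfg.votu_len[1] + 1)))
        for i in range(cfg.n_votus)
    }
    votu_ids = list(votus)

    genomes: list[GenomeRecord] = []
    genome_seqs: dict[str, str] = {}
    prophage_truth: list[ProphageRegion] = []
    crispr_truth: list[CrisprArray] = []
    linkage_truth: set[tuple[str, str]] = set()

    for si in range(cfg.n_species):
        species = f"sp{si:02d}"
        base_len = int(rng.integers(cfg.genome_len[0], cfg.genome_len[1] + 1))
        ancestor = _random_seq(rng, base_len)
        n_strains = int(rng.integers(cfg.strains_per_species[0], cfg.strains_per_species[1] + 1))
        for sj in range(n_strains):
            mag_id = f"{species}_str{sj}"
            seq_id = f"{mag_id}_c0"
            backbone = _mutate(rng, ancestor, cfg.strain_divergence) if sj else ancestor

            carries_prophage = rng.random() < cfg.prophage_rate
            carries_array = rng.random() < cfg.crispr_rate

            prophage_votu = votu_ids[rng.integers(cfg.n_votus)] if carries_prophage else None
            prophage_seq = votus[prophage_votu] if prophage_votu else ""
            needed = (2 * MIN_FLANK + len(prophage_seq)) if carries_prophage else 0
            if len(backbone) < max(needed, 2 * MIN_FLANK):
                raise ValueError(f"contig {seq_id}: genome too short for requested insertions")

            # Assemble the contig segment-wise so planted coordinates are exact.
            pieces: list[str] = []
            offset = 0

            if carries_prophage:
                cut = int(rng.integers(MIN_FLANK, len(backbone) - len(prophage_seq) - MIN_FLANK + 1))
            else:
                cut = len(backbone) // 2
            pieces.append(backbone[:cut])
            offset = cut
            if carries_prophage:
                prophage_truth.append(
                    ProphageRegion(
                        prophage_id=f"pp_{mag_id}",
                        host_mag=mag_id,
                        host_species=species,
                        seq_id=seq_id,
                        start=offset,
                        end=offset + len(prophage_seq),
                        category="checkv_integrated",
                        votu_id=prophage_votu,
                    )
                )
                pieces.append(prophage_seq)
                offset += len(prophage_seq)

            mid = backbone[cut:]
            if carries_array:
                # Keep the array clear of the prophage by placing it in the
                # right-hand host segment.
                split = len(mid) // 2
                pieces.append(mid[:split])
                offset += split
                array, links = _plant_crispr_array(
                    rng, cfg, seq_id, offset, votus, array_id=f"arr_{mag_id}"
                )
                crispr_truth.append(array)
                linkage_truth.update((mag_id, v) for v in links)
                array_seq = "".join(
                    seg for _, _, seg in sorted(array.repeats + array.spacers, key=lambda t: t[0])
                )
                pieces.append(array_seq)
                offset += len(array_seq)
                pieces.append(mid[split:])
            else:
                pieces.append(mid)

            genome_seqs[seq_id] = "".join(pieces)
            genomes.append(
                GenomeRecord(
                    mag_id=mag_id,
                    species=species,
                    strain_cluster=mag_id,
                    contigs=((seq_id, len(genome_seqs[seq_id])),),
                )
            )

    return CommunitySim(genomes, genome_seqs, votus, prophage_truth, crispr_truth, linkage_truth)


def _plant_crispr_array(
    rng: np.random.Generator,
    cfg: SimConfig,
    seq_id: str,
    offset: int,
    votus: Mapping[str, str],
    array_id: str,
) -> tuple[CrisprArray, set[str]]:
    """Write one repeat-spacer array starting at ``offset`` on the contig.

    Spacers sourced from a vOTU are >=30 bp (the linkable minimum); the rest
    are random in the 26-50 bp range.
    """
    repeat_len = int(rng.integers(23, 48))
    repeat = _random_seq(rng, repeat_len)
    n_spacers = int(rng.integers(3, 6))
    votu_ids = list(votus)
    linked: set[str] = set()

    repeats: list[tuple[int, int, str]] = []
    spacers: list[tuple[int, int, str]] = []
    pos = offset
    for k in range(n_spacers + 1):
        repeats.append((pos, pos + repeat_len, repeat))
        pos += repeat_len
        if k < n_spacers:
            if rng.random() < cfg.spacer_source_frac:
                votu_id = votu_ids[rng.integers(len(votu_ids))]
                length = int(rng.integers(30, 51))
                target = votus[votu_id]
                start = int(rng.integers(0, len(target) - length + 1))
                spacer = target[start : start + length]
                linked.add(votu_id)
            else:
                spacer = _random_seq(rng, int(rng.integers(26, 51)))
            spacers.append((pos, pos + len(spacer), spacer))
            pos += len(spacer)

    return CrisprArray(array_id, seq_id, repeats, spacers, repeat), linked


def simulate_abundances(
    cfg: SimConfig,
    design: list[SampleMeta],
    taxa: list[str] | None = None,
) -> AbundanceTable:
    """Log-normal per-sample proportions with group log2-fold effects, then
    multinomial read counts at each sample's ``total_reads``.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    if taxa is None:
        taxa = [f"sp{si:02d}" for si in range(cfg.n_species)]
    effects = {g: dict(e) for g, e in cfg.group_effects.items()}
    for s in design:
        if s.total_reads <= 0:
            raise ValueError(f"sample {s.sample_id}: non-positive total_reads")
        if effects and s.group and s.group not in effects:
            raise ValueError(f"sample {s.sample_id}: group {s.group!r} not in group_effects")

    base = rng.normal(0.0, 1.0, size=len(taxa))
    counts = np.zeros((len(design), len(taxa)), dtype=np.int64)
    for i, s in enumerate(design):
        logp = base + rng.normal(0.0, cfg.abundance_lognormal_sigma, size=len(taxa))
        if s.group in effects:
            for j, t in enumerate(taxa):
                logp[j] += np.log(2.0) * effects[s.group].get(t, 0.0)
        p = np.exp(logp - logp.max())
        p /= p.sum()
        counts[i] = rng.multinomial(s.total_reads, p)

    df = pd.DataFrame(counts, index=[s.sample_id for s in design], columns=taxa)
    return AbundanceTable(df, "read_count", samples=list(design))


def simulate_coverage(
    seq_id: str,
    length: int,
    target_depth: float,
    seed: int | np.random.Generator,
    prophage_region: tuple[int, int] | None = None,
    induction_factor: float = 1.0,
) -> CoverageProfile:
    """I.i.d. Poisson(target_depth) depth track; an optional prophage interval
    gets its rate multiplied by ``induction_factor`` (prophage induction).
    """
    if target_depth < 0:
        raise ValueError("negative depth")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lam = np.full(length, float(target_depth))
    if prophage_region is not None:
        start, end = prophage_region
        lam[start:end] *= induction_factor
    return CoverageProfile(seq_id, rng.poisson(lam))


def simulate_snvs(
    gene_codons: str,
    omega: float,
    mutation_rate: float,
    seed: int | np.random.Generator,
    depth: int = 20,
) -> list[SNVCall]:
    """Codon-level SNVs under selection.

    Candidate point mutations arise per site at ``mutation_rate`` and are
    accepted with probability proportional to 1 for synonymous and ``omega``
    for nonsynonymous changes; stop-introducing mutations are rejected.
    Positions are 0-based on the gene.
    """
    if len(gene_codons) % 3 != 0:
        raise ValueError("gene length not divisible by 3")
    if omega < 0:
        raise ValueError("omega must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    gene = gene_codons.upper()
    scale = 1.0 / max(1.0, omega)
    out: list[SNVCall] = []
    for pos in range(len(gene)):
        if rng.random() >= mutation_rate:
            continue
        ref = gene[pos]
        alt = "ACGT".replace(ref, "")[rng.integers(3)]
        ci = pos // 3
        codon = gene[3 * ci : 3 * ci + 3]
        mutated = codon[: pos % 3] + alt + codon[pos % 3 + 1 :]
        if codon in STOP_CODONS or mutated in STOP_CODONS:
            continue
        synonymous = CODON_TO_AA[mutated] == CODON_TO_AA[codon]
        accept_p = scale if synonymous else scale * omega
        if rng.random() < accept_p:
            count = max(1, int(round(rng.uniform(0.05, 0.5) * depth)))
            out.append(SNVCall(position=pos, ref=ref, alt=alt, allele_count=count, depth=depth))
    return out


def simulate_network_abundances(
    precision: np.ndarray,
    n_samples: int,
    depth: int,
    seed: int | np.random.Generator,
    taxa: list[str] | None = None,
) -> AbundanceTable:
    """Latent Gaussian draws with the given precision matrix, softmax to
    proportions, then multinomial counts. The truth edge set is the
    off-diagonal support of ``precision`` (:func:`precision_truth_edges`).
    """
    precision = np.asarray(precision, dtype=float)
    try:
        np.linalg.cholesky(precision)
    except np.linalg.LinAlgError as exc:
        raise ValueError("precision matrix is not positive-definite") from exc
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = precision.shape[0]
    cov = np.linalg.inv(precision)
    chol = np.linalg.cholesky(cov)
    z = rng.standard_normal((n_samples, p)) @ chol.T
    props = np.exp(z - z.max(axis=1, keepdims=True))
    props /= props.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(depth, row) for row in props])
    names = taxa if taxa is not None else [f"t{j:03d}" for j in range(p)]
    df = pd.DataFrame(counts, index=[f"s{i:03d}" for i in range(n_samples)], columns=names)
    return AbundanceTable(df, "read_count")


def precision_truth_edges(precision: np.ndarray, tol: float = 1e-12) -> set[tuple[int, int]]:
    """Off-diagonal support of a precision matrix as an undirected edge set."""
    precision = np.asarray(precision)
    p = precision.shape[0]
    return {
        (i, j) for i in range(p) for j in range(i + 1, p) if abs(precision[i, j]) > tol
    }


def chain_precision(p: int, rho: float = -0.45) -> np.ndarray:
    """Tridiagonal precision matrix: a chain of ``p - 1`` conditional dependencies."""
    theta = np.eye(p)
    idx = np.arange(p - 1)
    theta[idx, idx + 1] = rho
    theta[idx + 1, idx] = rho
    return theta


def coupled_virus_host_precision(
    n_microbes: int = 30,
    n_viruses: int = 15,
    n_phyla: int = 3,
    rho_within: float = 0.45,
    rho_vh: float = 0.45,
    hosts_per_virus: int = 2,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, list[str], list[str]]:
    """Precision matrix for a virus-microbe community.

    Microbes form within-phylum chains (an assortative microbe-only
    backbone); each virus couples to ``hosts_per_virus`` microbes drawn from
    distinct phyla and is labelled with the phylum of its first (designated)
    host — so most virus edges cross categories, mirroring how predicted-host
    phylum labels behave. Returns ``(precision, node_types, categories)``
    with microbes first, then viruses.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = n_microbes + n_viruses
    theta = np.eye(p)
    per_phylum = n_microbes // n_phyla
    categories = []
    for i in range(n_microbes):
        categories.append(f"phylum{min(i // per_phylum, n_phyla - 1)}")
    # within-phylum chains
    for i in range(n_microbes - 1):
        if categories[i] == categories[i + 1]:
            theta[i, i + 1] = theta[i + 1, i] = -rho_within
    # virus-host couplings across phyla
    phyla_members = {
        ph: [i for i, c in enumerate(categories) if c == ph] for ph in sorted(set(categories))
    }
    phyla = sorted(phyla_members)
    for v in range(n_viruses):
        vi = n_microbes + v
        chosen_phyla = [phyla[(v + k) % len(phyla)] for k in range(hosts_per_virus)]
        hosts = [phyla_members[ph][int(rng.integers(len(phyla_members[ph])))] for ph in chosen_phyla]
        for h in set(hosts):
            theta[vi, h] = theta[h, vi] = -rho_vh
        categories.append(categories[hosts[0]])  # predicted-host phylum label
    # Diagonal loading for positive-definiteness, preserving support.
    row_mass = np.abs(theta).sum(axis=1) - np.diag(theta)
    np.fill_diagonal(theta, np.maximum(1.0, 1.05 * row_mass))
    node_types = ["microbe"] * n_microbes + ["virus"] * n_viruses
    return theta, node_types, categories
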
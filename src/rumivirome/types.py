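"""Shared domain types for the rumen virus-microbe ecology pipeline.

All genomic coordinates are 0-based, half-open ``[start, end)`` — intervals,
prophage regions and spacer positions alike — so lengths are always
``end - start`` and adjacency needs no off-by-one care.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SampleMeta",
    "TaxonRecord",
    "AbundanceTable",
    "CoverageProfile",
    "GenomeRecord",
    "ContigAnnotation",
    "ProphageRegion",
    "VOTURecord",
    "CrisprArray",
    "SpacerMatch",
    "HostLinkage",
    "GeneModel",
    "SNVCall",
    "VHRRecord",
]

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample metadata: cohort group, optional blocking factor, library size."""

    sample_id: str
    group: str = ""
    block: str | None = None
    total_reads: int = 0
    total_bases: int = 0

    def __post_init__(self) -> None:
        if self.total_bases and self.total_reads and self.total_bases < self.total_reads:
            raise ValueError(
                f"sample {self.sample_id}: total_bases ({self.total_bases}) "
                f"< total_reads ({self.total_reads})"
            )


@dataclass(frozen=True)
class TaxonRecord:
    """A taxon with a GTDB-style lineage (domain..species, at most 7 ranks)."""

    taxon_id: str
    lineage: tuple[str, ...] = ()
    phylum: str = ""

    def __post_init__(self) -> None:
        if len(self.lineage) > 7:
            raise ValueError(f"taxon {self.taxon_id}: lineage has >7 ranks")
        if len(self.lineage) >= 2 and self.phylum and self.lineage[1] != self.phylum:
            raise ValueError(
                f"taxon {self.taxon_id}: phylum field {self.phylum!r} does not "
                f"match lineage phylum rank {self.lineage[1]!r}"
            )

    @property
    def genus(self) -> str:
        return self.lineage[5] if len(self.lineage) >= 6 else ""


VALUE_KINDS = ("read_count", "relative_abundance", "trimmed_mean_coverage")


@dataclass
class AbundanceTable:
    """Sample x taxon matrix of counts, relative abundances, or coverages.

    ``values`` is a pandas DataFrame indexed by sample_id with taxon/vOTU ids
    as columns. ``samples`` holds metadata aligned with the index; ``taxa``
    optionally holds :class:`TaxonRecord` annotations aligned with columns.
    """

    values: pd.DataFrame
    value_kind: str = "read_count"
    samples: list[SampleMeta] = field(default_factory=list)
    taxa: list[TaxonRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.value_kind not in VALUE_KINDS:
            raise ValueError(f"unknown value_kind {self.value_kind!r}")
        if (self.values.values < 0).any():
            raise ValueError("abundance table has negative entries")
        if self.value_kind == "relative_abundance":
            sums = self.values.sum(axis=1).to_numpy()
            nonzero = sums > 0
            if not np.allclose(sums[nonzero], 1.0, atol=1e-9):
                raise ValueError("relative_abundance rows must sum to 1 +- 1e-9")
        if self.samples and len(self.samples) != len(self.values.index):
            raise ValueError("samples metadata does not match table rows")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.values.columns)

    def relative(self) -> "AbundanceTable":
        """Return the table as per-sample proportions of classified reads."""
        if self.value_kind == "relative_abundance":
            return self
        if self.value_kind != "read_count":
            raise ValueError("cannot renormalize a coverage table")
        sums = self.values.sum(axis=1)
        rel = self.values.div(sums.replace(0, np.nan), axis=0).fillna(0.0)
        return AbundanceTable(rel, "relative_abundance", self.samples, self.taxa)

    def meta_by_id(self) -> dict[str, SampleMeta]:
        return {m.sample_id: m for m in self.samples}


@dataclass
class CoverageProfile:
    """Per-position read depth track for one sequence (CoverM-style summary carrier)."""

    seq_id: str
    depths: np.ndarray

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths)
        if self.depths.ndim != 1:
            raise ValueError("depths must be one-dimensional")
        if len(self.depths) and (self.depths < 0).any():
            raise ValueError(f"{self.seq_id}: negative depth")

    @property
    def length(self) -> int:
        return len(self.depths)


@dataclass(frozen=True)
class GenomeRecord:
    """A MAG: the unit of a microbial strain after 98%-ANI secondary clustering."""

    mag_id: str
    species: str
    strain_cluster: str
    contigs: tuple[tuple[str, int], ...]  # (seq_id, length)

    def __post_init__(self) -> None:
        if sum(length for _, length in self.contigs) <= 0:
            raise ValueError(f"MAG {self.mag_id}: total genome length must be > 0")

    @property
    def contig_ids(self) -> tuple[str, ...]:
        return tuple(seq_id for seq_id, _ in self.contigs)

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.contigs)


@dataclass
class ContigAnnotation:
    """External viral-discovery annotations on one contig.

    ``genes`` holds ``(start, end, strand, vog_ids)`` entries; ``provirus_region``
    is a CheckV-style integrated-provirus interval when ``provirus_flag`` is set.
    """

    seq_id: str
    length: int
    genes: list[tuple[int, int, str, frozenset[str]]] = field(default_factory=list)
    provirus_flag: bool = False
    provirus_region: tuple[int, int] | None = None
    source_mag: str = ""
    host_species: str = ""

    def __post_init__(self) -> None:
        for start, end, _, _ in self.genes:
            if not (0 <= start < end <= self.length):
                raise ValueError(f"{self.seq_id}: gene interval [{start},{end}) out of bounds")


@dataclass
class ProphageRegion:
    """A called prophage on a host contig."""

    prophage_id: str
    host_mag: str
    host_species: str
    seq_id: str
    start: int
    end: int
    category: str  # checkv_integrated | marker_gene
    markers_found: frozenset[str] = frozenset()
    votu_id: str | None = None
    activity: str = "untested"  # active | cryptic | untested

    def __post_init__(self) -> None:
        if self.end - self.start <= 0:
            raise ValueError(f"{self.prophage_id}: empty interval")
        if self.category == "marker_gene" and not self.markers_found:
            raise ValueError(f"{self.prophage_id}: marker_gene category requires markers")
        if self.category not in ("checkv_integrated", "marker_gene"):
            raise ValueError(f"{self.prophage_id}: unknown category {self.category!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class VOTURecord:
    """A viral OTU: cluster of sequences at >=95% ANI over >=85% of the shorter."""

    votu_id: str
    representative: str
    members: frozenset[str]
    rep_length: int

    def __post_init__(self) -> None:
        if self.representative not in self.members:
            raise ValueError(f"{self.votu_id}: representative not among members")


@dataclass
class CrisprArray:
    """A detected repeat-spacer array on a microbial contig."""

    array_id: str
    seq_id: str
    repeats: list[tuple[int, int, str]]  # (start, end, sequence)
    spacers: list[tuple[int, int, str]]
    consensus_repeat: str

    def __post_init__(self) -> None:
        if len(self.repeats) < 3:
            raise ValueError(f"{self.array_id}: fewer than 3 repeats")
        if len(self.spacers) != len(self.repeats) - 1:
            raise ValueError(f"{self.array_id}: spacer count must be repeat count - 1")

    @property
    def spacer_sequences(self) -> list[str]:
        return [seq for _, _, seq in self.spacers]


@dataclass(frozen=True)
class SpacerMatch:
    """A spacer-to-vOTU protospacer hit (full-length, ungapped)."""

    spacer_id: str  # "<array_id>:<ordinal>"
    votu_id: str
    position: int  # 0-based on the vOTU forward strand
    strand: str  # "+" or "-"
    mismatches: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        if self.mismatches not in (0, 1):
            raise ValueError("only 0- and 1-mismatch hits are reported")


@dataclass
class HostLinkage:
    """A (strain, vOTU) pair backed by a zero-mismatch spacer match plus co-occurrence."""

    mag_id: str
    votu_id: str
    supporting_samples: frozenset[str]
    spacer_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.supporting_samples:
            raise ValueError(f"linkage {self.mag_id}-{self.votu_id}: no supporting samples")


@dataclass
class GeneModel:
    """A protein-coding gene carried on a contig; sequence given in reference frame."""

    gene_id: str
    seq_id: str
    start: int
    end: int
    strand: str
    codons: str  # nucleotide sequence, length divisible by 3

    def __post_init__(self) -> None:
        if len(self.codons) % 3 != 0:
            raise ValueError(f"{self.gene_id}: length not divisible by 3")
        if self.end - self.start != len(self.codons):
            raise ValueError(f"{self.gene_id}: interval does not match sequence length")


@dataclass(frozen=True)
class SNVCall:
    """A single-nucleotide variant observed in a read population."""

    position: int  # 0-based on contig
    ref: str
    alt: str
    allele_count: int
    depth: int

    def __post_init__(self) -> None:
        if self.alt == self.ref:
            raise ValueError("alt equals ref")
        if not (0 < self.allele_count <= self.depth):
            raise ValueError("need 0 < allele_count <= depth")


@dataclass
class VHRRecord:
    """One virus-to-host ratio observation for a (prophage vOTU, host) linkage."""

    votu_id: str
    host_taxon: str
    sample_id: str
    prophage_cov: float
    host_reads: int
    group: str = ""

    @property
    def vhr(self) -> float:
        if self.host_reads <= 0:
            return float("nan")
        return self.prophage_cov / self.host_reads
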
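"""Strand-aware extraction of upstream regions and assembly of the
positive/control discovery sets.

Upstream regions are anchored at the translation start (first base of the
start codon) so the extracted stretch implicitly includes the 5' UTR. All
coordinates are 0-based half-open. When the contig runs out before the
requested length, the longest available stretch is extracted and the record
is flagged truncated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from ._sequence import revcomp
from .phylotrait import SpeciesStatus

log = logging.getLogger(__name__)

FOCAL_FAMILY = "NIN"


class EmptyPositiveSetError(ValueError):
    """Raised when a discovery design yields no positive promoters."""


@dataclass(frozen=True)
class GeneRecord:
    """One row of the gene coordinate table."""

    gene_id: str
    species_id: str
    family: str  # focal "NIN", paralogue "NLP", or other (e.g. "ERN1")
    contig: str
    strand: str  # "+" or "-"
    translation_start: int  # 0-based genomic coordinate, gene orientation
    length_override: int | None = None  # per-gene upstream-length exception

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class PromoterRecord:
    gene_id: str
    species_id: str
    family: str
    sequence: str
    requested_length: int
    actual_length: int
    truncated: bool

    def __post_init__(self) -> None:
        if self.actual_length != len(self.sequence):
            raise ValueError("actual_length must equal len(sequence)")
        if self.actual_length > self.requested_length:
            raise ValueError("actual_length cannot exceed requested_length")
        if self.truncated != (self.actual_length < self.requested_length):
            raise ValueError("truncated flag inconsistent with lengths")


@dataclass
class DiscoverySets:
    positives: list[PromoterRecord]
    controls: list[PromoterRecord]
    design: str

    def __post_init__(self) -> None:
        pos_ids = {p.gene_id for p in self.positives}
        if pos_ids & {c.gene_id for c in self.controls}:
            raise ValueError("positives and controls overlap by gene_id")


def extract_upstream(
    genome: Mapping[str, str], gene: GeneRecord, L: int | None = None
) -> PromoterRecord:
    """Extract up to L bases upstream of the translation start.

    For a + strand gene at 0-based start t the region is contig[max(0,t-L):t)
    in genomic orientation; for a - strand gene it is the reverse complement
    of contig[t+1 : min(len,t+1+L)). Non-ACGT characters are uppercased and
    preserved.
    """
    if L is None:
        L = 3000
    if gene.length_override is not None:
        L = gene.length_override
    if L < 1:
        raise ValueError("upstream length L must be >= 1")
    if gene.contig not in genome:
        raise KeyError(f"contig {gene.contig!r} not found in genome")
    contig = genome[gene.contig]
    t = gene.translation_start
    if not 0 <= t <= len(contig):
        raise IndexError(
            f"translation_start {t} out of bounds for contig {gene.contig!r} "
            f"(length {len(contig)})"
        )
    if gene.strand == "+":
        seq = contig[max(0, t - L) : t]
    else:
        seq = revcomp(contig[t + 1 : min(len(contig), t + 1 + L)])
    seq = seq.upper()
    return PromoterRecord(
        gene_id=gene.gene_id,
        species_id=gene.species_id,
        family=gene.family,
        sequence=seq,
        requested_length=L,
        actual_length=len(seq),
        truncated=len(seq) < L,
    )


def build_sets(
    promoters: Sequence[PromoterRecord],
    species: Sequence[SpeciesStatus],
    design: str = "discriminative",
    *,
    focal_family: str = FOCAL_FAMILY,
    best_per_species: Mapping[str, str] | None = None,
) -> DiscoverySets:
    """Partition promoters into positives/controls for a discovery design.

    discriminative : positives = focal-family promoters of trait-positive
        clade species; controls = focal-family promoters of non-clade
        species plus all paralogue-family promoters.
    normal : same positives, empty controls.
    one_per_species : positives restricted to the single best-scoring
        promoter per species as given by `best_per_species`
        (species_id -> gene_id, from a prior scan); controls as
        discriminative.
    """
    status = {s.species_id: s for s in species}
    missing = sorted({p.species_id for p in promoters} - status.keys())
    if missing:
        raise KeyError(f"promoters reference species without a status entry: {missing}")

    positives: list[PromoterRecord] = []
    controls: list[PromoterRecord] = []
    excluded: list[PromoterRecord] = []

    for p in promoters:
        st = status[p.species_id]
        if p.family == focal_family and st.clade and st.trait:
            positives.append(p)
        elif design == "normal":
            excluded.append(p)
        elif p.family != focal_family or not st.clade:
            controls.append(p)
        else:
            excluded.append(p)  # focal promoters of trait-negative clade species

    if design == "one_per_species":
        if best_per_species is None:
            raise ValueError("design 'one_per_species' requires best_per_species mapping")
        keep = set(best_per_species.values())
        positives = [p for p in positives if p.gene_id in keep]
    elif design not in ("discriminative", "normal"):
        raise ValueError(f"unknown design {design!r}")

    if not positives:
        raise EmptyPositiveSetError(
            f"design {design!r} produced an empty positive set"
        )
    log.info(
        "build_sets(%s): %d positives, %d controls, %d excluded",
        design, len(positives), len(controls), len(excluded),
    )
    return DiscoverySets(positives=positives, controls=controls, design=design)
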
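"""Presence/absence on a species tree: predisposition criteria, Dollo
single-gain reconstruction, and trait-loss attribution.

The two predisposition criteria for a candidate element are (1) exclusive
presence inside the designated clade and (2) conservation throughout the
clade, or at least in every trait-positive (nodulating) member. Dollo
parsimony allows exactly one gain and any number of subsequent losses, so
the gain maps to the most recent common ancestor of the present leaves and
the losses to the minimal set of pruned branches below it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy

log = logging.getLogger(__name__)

ORF_STATES = ("full_length", "disrupted", "absent")


class NoLossError(ValueError):
    """Raised when loss attribution is requested but no species lost the trait."""


@dataclass(frozen=True)
class SpeciesStatus:
    """Per-species clade membership, trait state and focal-gene ORF state."""

    species_id: str
    clade: bool
    trait: bool  # True = nodulating / trait-positive
    orf_status: str = "full_length"

    def __post_init__(self) -> None:
        if self.orf_status not in ORF_STATES:
            raise ValueError(f"orf_status must be one of {ORF_STATES}")


@dataclass
class CriteriaReport:
    criterion1: bool  # exclusively present inside the clade
    criterion2: bool  # present in every trait-positive clade species
    specificity: bool  # absent from every paralogue promoter
    outside_hits: list[str] = field(default_factory=list)
    missing_nodulators: list[str] = field(default_factory=list)
    paralogue_hits: list[tuple[str, str]] = field(default_factory=list)
    reason: str = ""

    @property
    def all_pass(self) -> bool:
        return self.criterion1 and self.criterion2


@dataclass
class DolloResult:
    gain_node: dendropy.Node | None
    n_losses: int

    @property
    def gain_leafset(self) -> frozenset[str]:
        if self.gain_node is None:
            return frozenset()
        return frozenset(l.taxon.label for l in self.gain_node.leaf_iter())


@dataclass
class AttributionSummary:
    n_loss: int
    n_orf: int
    n_full_orf: int
    n_motif: int
    n_unexplained: int
    orf_pct: int
    motif_pct: int
    combined_pct: int
    orf_frac: float
    motif_frac: float
    combined_frac: float


def _round_half_away(x: float) -> int:
    import math

    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def criteria_check(
    presence: Mapping[str, bool],
    paralogue_presence: Mapping[tuple[str, str], bool] | None,
    species: Sequence[SpeciesStatus],
) -> CriteriaReport:
    """Evaluate the predisposition criteria on focal-gene presence calls.

    presence maps species_id -> motif present in its focal-gene promoter;
    paralogue_presence maps (species_id, gene_id) -> present for paralogue
    promoters (may be None when no paralogues were scanned).
    """
    status = {s.species_id: s for s in species}
    unknown = sorted(set(presence) - set(status))
    if unknown:
        raise KeyError(f"presence entries without species status: {unknown}")

    outside_hits = sorted(
        sp for sp, pres in presence.items() if pres and not status[sp].clade
    )
    nodulators = [s.species_id for s in species if s.clade and s.trait]
    missing = sorted(sp for sp in nodulators if not presence.get(sp, False))

    criterion1 = not outside_hits
    if nodulators:
        criterion2 = not missing
        reason = "" if criterion2 else "trait-positive clade species without the motif"
    else:
        criterion2 = False
        reason = "no trait-positive clade species in input"

    paralogue_hits = []
    if paralogue_presence:
        paralogue_hits = sorted(k for k, pres in paralogue_presence.items() if pres)
    specificity = not paralogue_hits

    return CriteriaReport(
        criterion1=criterion1,
        criterion2=criterion2,
        specificity=specificity,
        outside_hits=outside_hits,
        missing_nodulators=missing,
        paralogue_hits=paralogue_hits,
        reason=reason,
    )


def dollo_gains(tree: dendropy.Tree, present: Iterable[str]) -> DolloResult:
    """Single-gain Dollo reconstruction of a presence pattern.

    The gain node is the MRCA of the present leaves; n_losses is the number
    of maximal subtrees below the gain node containing no present leaf
    (each pruned by one loss on its stem branch). Polytomies are fine.
    """
    present = set(present)
    if not present:
        return DolloResult(gain_node=None, n_losses=0)
    tree.is_rooted = True  # reconstruction is defined on the seed-node root
    labels = {l.taxon.label for l in tree.leaf_node_iter()}
    unknown = sorted(present - labels)
    if unknown:
        raise KeyError(f"present leaves not in tree: {unknown}")

    if len(present) == 1:
        (only,) = present
        gain = next(l for l in tree.leaf_node_iter() if l.taxon.label == only)
        return DolloResult(gain_node=gain, n_losses=0)

    taxa = [tree.taxon_namespace.get_taxon(lbl) for lbl in sorted(present)]
    gain = tree.mrca(taxa=taxa)

    def count_losses(node: dendropy.Node) -> int:
        if node.is_leaf():
            return 0 if node.taxon.label in present else 1
        n = 0
        any_present = False
        child_losses = 0
        for child in node.child_nodes():
            has = any(l.taxon.label in present for l in child.leaf_iter())
            if has:
                any_present = True
                child_losses += count_losses(child)
            else:
                child_losses += 1  # prune whole subtree with one loss
        assert any_present  # gain node is MRCA of present leaves
        return n + child_losses

    return DolloResult(gain_node=gain, n_losses=count_losses(gain))


def attribute_losses(
    species: Sequence[SpeciesStatus], presence: Mapping[str, bool]
) -> AttributionSummary:
    """Classify every trait loss (trait-negative clade species) as
    ORF-attributed (disrupted or absent ORF), motif-attributed (full ORF but
    motif absent) or unexplained; report integer-rounded percentages.

    Species with an absent ORF have no promoter to scan and are counted on
    the ORF side without consulting `presence`.
    """
    losses = [s for s in species if s.clade and not s.trait]
    if not losses:
        raise NoLossError("no trait-negative clade species: nothing to attribute")

    n_orf = n_motif = n_unexplained = 0
    for s in losses:
        if s.orf_status in ("disrupted", "absent"):
            n_orf += 1
        elif not presence.get(s.species_id, False):
            n_motif += 1
        else:
            n_unexplained += 1

    n_loss = len(losses)
    n_full_orf = n_loss - n_orf
    orf_frac = n_orf / n_loss
    motif_frac = n_motif / n_loss
    combined_frac = (n_orf + n_motif) / n_loss
    return AttributionSummary(
        n_loss=n_loss,
        n_orf=n_orf,
        n_full_orf=n_full_orf,
        n_motif=n_motif,
        n_unexplained=n_unexplained,
        orf_pct=_round_half_away(100 * orf_frac),
        motif_pct=_round_half_away(100 * motif_frac),
        combined_pct=_round_half_away(100 * combined_frac),
        orf_frac=orf_frac,
        motif_frac=motif_frac,
        combined_frac=combined_frac,
    )
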
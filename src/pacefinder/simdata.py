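"""Seeded synthetic worlds for the clade-restricted promoter-motif analysis.

Generates a rooted ultrametric species phylogeny with a designated
monophyletic clade, per-species promoter sets (one focal-gene promoter plus
paralogue promoters), a ~29-bp element implanted only in clade members,
per-species sequence divergence that scales with root-to-leaf path length,
and trait-loss events attributed to ORF disruption, element loss, or
neither. A machine-readable ground-truth ledger records every implant and
every loss cause so each downstream stage can be validated.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from ._sequence import decode, encode, require_acgt
from .phylotrait import SpeciesStatus
from .promoters import PromoterRecord

#: arbitrary fixed 29-bp truth element used as the default implant; the
#: central CCCG..GGC-free core is meaningless, it just has to be a constant.
DEFAULT_TRUTH_MOTIF = "CTCGAGATGTTCCATGTGGTAACGCAGAT"

LOSS_CAUSES = ("orf", "motif", "other")


@dataclass(frozen=True)
class SimConfig:
    """Stated world of the simulator. Defaults are the conditions the
    end-to-end recovery analysis assumes: 20 clade + 20 outgroup species,
    2 paralogues each, 3-kb promoters, a 29-bp implant at 10% divergence."""

    n_clade_species: int = 20
    n_outgroup_species: int = 20
    n_paralogues_per_species: int = 2
    promoter_length: int = 3000
    background_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    truth_motif: str = DEFAULT_TRUTH_MOTIF
    per_branch_substitution_rate: float = 0.1
    loss_fraction: float = 0.3
    loss_cause_probs: tuple[float, float, float] = (0.64, 0.18, 0.18)
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_clade_species < 1 or self.n_outgroup_species < 1:
            raise ValueError("species counts must be >= 1")
        if self.n_paralogues_per_species < 1:
            raise ValueError("n_paralogues_per_species must be >= 1")
        bg = np.asarray(self.background_freqs, dtype=float)
        if bg.shape != (4,) or (bg < 0).any() or (bg > 1).any() or abs(bg.sum() - 1) > 1e-9:
            raise ValueError("background_freqs must be 4 probabilities summing to 1")
        lcp = np.asarray(self.loss_cause_probs, dtype=float)
        if lcp.shape != (3,) or (lcp < 0).any() or abs(lcp.sum() - 1) > 1e-9:
            raise ValueError("loss_cause_probs must be 3 probabilities summing to 1")
        if not 0.0 <= self.per_branch_substitution_rate <= 1.0:
            raise ValueError("per_branch_substitution_rate must be in [0, 1]")
        if not 0.0 <= self.loss_fraction <= 1.0:
            raise ValueError("loss_fraction must be in [0, 1]")
        require_acgt(self.truth_motif, what="truth_motif")
        if self.promoter_length < len(self.truth_motif):
            raise ValueError("promoter_length must be >= motif width")


@dataclass
class SimTruth:
    """Ground-truth ledger: implants, statuses, loss causes, tree."""

    implants: pd.DataFrame  # columns: species_id, gene_id, offset, sequence
    statuses: list[SpeciesStatus]
    loss_causes: dict[str, str]  # species_id -> orf|motif|other
    tree_newick: str
    config: SimConfig


@dataclass
class SimBundle:
    promoters: list[PromoterRecord]
    statuses: list[SpeciesStatus]
    tree: dendropy.Tree
    truth: SimTruth


def sim_tree(n_species: int, seed: int, prefix: str = "T") -> dendropy.Tree:
    """Rooted, bifurcating, ultrametric pure-birth (Yule) tree with
    n_species leaves named {prefix}01, {prefix}02, ... Deterministic in
    (n_species, seed)."""
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    rng = random.Random(seed)
    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_species,
        rng=rng,
    )
    tree.is_rooted = True
    width = max(2, len(str(n_species)))
    taxa = dendropy.TaxonNamespace()
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon = taxa.new_taxon(label=f"{prefix}{i:0{width}d}")
    tree.taxon_namespace = taxa
    return tree


def degrade_sequence(s: str, rate: float, seed: int) -> str:
    """Independently substitute each site with probability `rate`; a
    substituted site becomes a uniform draw over the three other bases."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    codes = require_acgt(s)
    return decode(_degrade(codes, rate, np.random.default_rng(seed)))


def _degrade(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    hit = rng.random(codes.shape[0]) < rate
    shift = rng.integers(1, 4, size=codes.shape[0], dtype=np.int8)
    out = codes.copy()
    out[hit] = (codes[hit] + shift[hit]) % 4
    return out


def _random_background(length: int, freqs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    return rng.choice(4, size=length, p=freqs).astype(np.int8)


def _scale_to_depth(tree: dendropy.Tree, depth: float) -> None:
    current = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
    factor = depth / current if current > 0 else 0.0
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= factor


def _species_tree(cfg: SimConfig, seed: int) -> tuple[dendropy.Tree, list[str], list[str]]:
    """Joint tree: a clade subtree (C..) and an outgroup subtree (O..),
    sister to each other, unit root-to-leaf depth."""
    clade = sim_tree(cfg.n_clade_species, seed, prefix="C")
    outgrp = sim_tree(cfg.n_outgroup_species, seed + 1, prefix="O")
    _scale_to_depth(clade, 0.8)
    _scale_to_depth(outgrp, 0.8)

    def _subtree_newick(t: dendropy.Tree) -> str:
        s = t.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()
        return s.rstrip(";")

    newick = f"({_subtree_newick(clade)}:0.2,{_subtree_newick(outgrp)}:0.2);"
    joint = dendropy.Tree.get(data=newick, schema="newick")
    joint.is_rooted = True
    clade_ids = sorted(
        l.taxon.label for l in joint.leaf_node_iter() if l.taxon.label.startswith("C")
    )
    out_ids = sorted(
        l.taxon.label for l in joint.leaf_node_iter() if l.taxon.label.startswith("O")
    )
    return joint, clade_ids, out_ids


def sim_bundle(cfg: SimConfig | None = None) -> SimBundle:
    """Generate the full synthetic bundle: promoters, species metadata,
    tree, and the ground-truth ledger.

    Every trait-positive clade species carries exactly one implant (the
    truth element degraded at rate * root-to-leaf path length) at a uniform
    offset in its focal-gene promoter; trait-negative clade species keep or
    lose the implant according to their assigned loss cause; no outgroup or
    paralogue promoter ever carries an implant.
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    bg = np.asarray(cfg.background_freqs, dtype=float)
    motif_codes = encode(cfg.truth_motif)
    w = motif_codes.shape[0]
    L = cfg.promoter_length

    tree, clade_ids, out_ids = _species_tree(cfg, int(rng.integers(0, 2**31 - 1)))
    depth = {leaf.taxon.label: leaf.distance_from_root() for leaf in tree.leaf_node_iter()}

    n_loss = int(round(cfg.loss_fraction * cfg.n_clade_species))
    losers = sorted(rng.choice(clade_ids, size=n_loss, replace=False).tolist())
    causes = {
        sp: LOSS_CAUSES[i]
        for sp, i in zip(losers, rng.choice(3, size=n_loss, p=np.asarray(cfg.loss_cause_probs)))
    }

    statuses: list[SpeciesStatus] = []
    promoters: list[PromoterRecord] = []
    implant_rows: list[dict] = []

    for sp in clade_ids + out_ids:
        in_clade = sp in set(clade_ids)
        cause = causes.get(sp)
        trait = in_clade and cause is None
        orf = "disrupted" if cause == "orf" else "full_length"
        statuses.append(SpeciesStatus(species_id=sp, clade=in_clade, trait=trait, orf_status=orf))

        # focal promoter
        seq = _random_background(L, bg, rng)
        wants_implant = in_clade and (trait or cause in ("orf", "other"))
        gene_id = f"{sp}_NIN"
        if wants_implant:
            rate = cfg.per_branch_substitution_rate * depth[sp]
            implant = _degrade(motif_codes, rate, rng)
            offset = int(rng.integers(0, L - w + 1))
            seq[offset : offset + w] = implant
            implant_rows.append(
                {"species_id": sp, "gene_id": gene_id, "offset": offset, "sequence": decode(implant)}
            )
        promoters.append(
            PromoterRecord(
                gene_id=gene_id, species_id=sp, family="NIN",
                sequence=decode(seq), requested_length=L, actual_length=L, truncated=False,
            )
        )
        for k in range(1, cfg.n_paralogues_per_species + 1):
            pseq = _random_background(L, bg, rng)
            promoters.append(
                PromoterRecord(
                    gene_id=f"{sp}_NLP{k}", species_id=sp, family="NLP",
                    sequence=decode(pseq), requested_length=L, actual_length=L, truncated=False,
                )
            )

    implants = pd.DataFrame(implant_rows, columns=["species_id", "gene_id", "offset", "sequence"])
    newick = tree.as_string(schema="newick", suppress_rooting=True).strip()
    truth = SimTruth(
        implants=implants, statuses=statuses, loss_causes=causes, tree_newick=newick, config=cfg
    )
    return SimBundle(promoters=promoters, statuses=statuses, tree=tree, truth=truth)
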
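"""End-to-end orchestration: configuration, file I/O, reproducible runs.

`simulate` writes a synthetic bundle (promoters, metadata, tree, truth
ledger); `run_pipeline` ties extraction/loading, the four-pass discovery
protocol, scanning, the predisposition criteria, Dollo reconstruction and
loss attribution together, writing every artifact plus a checksum manifest.
A single global seed governs all stochastic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .motifdisc import DiscoveryConfig, ProtocolConfig, run_pace_protocol
from .motifscan import scan
from .phylotrait import attribute_losses, criteria_check, dollo_gains
from .promoters import FOCAL_FAMILY
from .simdata import SimBundle, SimConfig, sim_bundle

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Run parameters; defaults follow the analysis they reproduce
    (3-kb upstream regions, 29-bp core motif refined from a 45-bp search,
    q <= 0.1 presence calls)."""

    promoters: str = ""
    metadata: str = ""
    tree: str = ""
    out_dir: str = "pipeline_out"
    upstream_length: int = 3000
    core_width: int = 29
    wide_width: int = 45
    width_grid: tuple[int, ...] = tuple(range(6, 51))
    fdr: float = 0.1
    pseudocount: float = 0.25
    em_tol: float = 1e-6
    em_max_iter: int = 200
    max_seeds: int = 2000
    n_motifs: int = 1
    seed: int = 42

    def __post_init__(self) -> None:
        if self.core_width < 4 or self.wide_width < self.core_width:
            raise ValueError("need wide_width >= core_width >= 4")
        if not 0 < self.fdr <= 1:
            raise ValueError("fdr must be in (0, 1]")
        if self.em_tol <= 0 or self.em_max_iter < 1 or self.max_seeds < 1:
            raise ValueError("EM parameters out of domain")

    def protocol_config(self) -> ProtocolConfig:
        return ProtocolConfig(
            core_width=self.core_width,
            wide_width=self.wide_width,
            width_grid=tuple(self.width_grid),
            fdr=self.fdr,
            discovery=DiscoveryConfig(
                max_seeds=self.max_seeds,
                pseudocount=self.pseudocount,
                tol=self.em_tol,
                max_iter=self.em_max_iter,
                seed=self.seed,
            ),
        )

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["width_grid"] = list(self.width_grid)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "width_grid" in d:
            d["width_grid"] = tuple(d["width_grid"])
        return cls(**d)


def simulate(config: SimConfig, out_dir: str | Path) -> Path:
    """Write the synthetic bundle (promoter FASTA, metadata TSV, Newick
    tree, truth-implant ledger TSV) into out_dir; returns the directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = sim_bundle(config)
    write_bundle(bundle, out)
    return out


def write_bundle(bundle: SimBundle, out: Path) -> None:
    pio.write_promoter_fasta(bundle.promoters, out / "promoters.fasta")
    pio.write_metadata(bundle.statuses, out / "metadata.tsv")
    pio.write_tree(bundle.tree, out / "tree.nwk")
    bundle.truth.implants.to_csv(out / "truth_implants.tsv", sep="\t", index=False)
    causes = pd.DataFrame(
        sorted(bundle.truth.loss_causes.items()), columns=["species_id", "loss_cause"]
    )
    causes.to_csv(out / "truth_loss_causes.tsv", sep="\t", index=False)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Run discovery -> scan -> evaluation end to end and write artifacts.

    Inputs are a promoter FASTA ('species|gene|family' headers), a species
    metadata TSV and a rooted Newick tree. Outputs land in config.out_dir
    with a manifest of sha256 checksums.
    """
    for label, p in (("promoters", config.promoters),
                     ("metadata", config.metadata), ("tree", config.tree)):
        if not p or not Path(p).exists():
            raise FileNotFoundError(f"{label} file not found: {p!r}")

    promoters = pio.read_promoter_fasta(config.promoters)
    species = pio.read_metadata(config.metadata)
    tree = pio.read_tree(config.tree)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    report = run_pace_protocol(promoters, species, tree, config.protocol_config())
    final_pwm = report.final_pwm

    hits, calls = scan(final_pwm, promoters, fdr=config.fdr)

    focal = {c.species_id: c.present for c in calls if c.family == FOCAL_FAMILY}
    paralogue = {
        (c.species_id, c.gene_id): c.present
        for c in calls if c.family != FOCAL_FAMILY
    }
    criteria = criteria_check(focal, paralogue, species)
    status = {s.species_id: s for s in species}
    present_leaves = {sp for sp, pres in focal.items() if pres}
    dollo = dollo_gains(tree, present_leaves)
    attribution = attribute_losses(species, focal)

    # ---- write artifacts -------------------------------------------------
    config.to_yaml(out / "config.yaml")
    pio.write_pwm_meme(final_pwm, out / "final_motif.meme.txt", name="FINAL")
    pio.write_pwm_tsv(final_pwm, out / "final_motif.tsv")

    pd.DataFrame(
        [dataclasses.asdict(h) for h in hits]
    ).to_csv(out / "hits.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"species_id": c.species_id, "gene_id": c.gene_id, "family": c.family,
             "status": c.status,
             "q": c.best_hit.q if c.best_hit else np.nan,
             "p": c.best_hit.p if c.best_hit else np.nan}
            for c in calls
        ]
    ).to_csv(out / "presence_calls.tsv", sep="\t", index=False)

    passes_df = pd.DataFrame(
        [
            {"pass": p.name, "design": p.design, "mode": p.mode,
             "widths": ",".join(map(str, p.widths)),
             "width": p.model.width, "consensus": p.model.consensus,
             "objective_bits": p.model.objective,
             "significance": p.model.significance, "gamma": p.model.gamma}
            for p in report.passes
        ]
    )
    passes_df.to_csv(out / "protocol_report.tsv", sep="\t", index=False)

    evaluation = {
        "criteria": {
            "criterion1_clade_exclusive": criteria.criterion1,
            "criterion2_conserved_in_nodulators": criteria.criterion2,
            "paralogue_specificity": criteria.specificity,
            "outside_hits": criteria.outside_hits,
            "missing_nodulators": criteria.missing_nodulators,
        },
        "dollo": {
            "gain_leafset": sorted(dollo.gain_leafset),
            "n_losses": dollo.n_losses,
        },
        "attribution": dataclasses.asdict(attribution),
        "one_per_species": report.one_per_species,
    }
    (out / "evaluation.json").write_text(json.dumps(evaluation, indent=2) + "\n")

    attr_df = pd.DataFrame([dataclasses.asdict(attribution)])
    attr_df.to_csv(out / "attribution.tsv", sep="\t", index=False)

    pd.DataFrame(
        [
            {"check": "criterion1_clade_exclusive", "passed": criteria.criterion1,
             "violations": ";".join(criteria.outside_hits)},
            {"check": "criterion2_conserved_in_nodulators", "passed": criteria.criterion2,
             "violations": ";".join(criteria.missing_nodulators)},
            {"check": "paralogue_specificity", "passed": criteria.specificity,
             "violations": ";".join(f"{sp}|{g}" for sp, g in criteria.paralogue_hits)},
        ]
    ).to_csv(out / "criteria.tsv", sep="\t", index=False)

    manifest = {
        p.name: _sha256(p)
        for p in sorted(out.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    log.info("pipeline complete: %d artifacts in %s", len(manifest), out)
    return out
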
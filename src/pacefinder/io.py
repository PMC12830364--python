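"""Readers and writers for the pipeline's plain-text exchange formats.

FASTA goes through Biopython (60-column wrapping), tables through pandas
(tab-delimited, UTF-8, with header), trees through dendropy Newick, and
PWMs through MEME-minimal-compatible text plus a TSV twin.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .phylotrait import SpeciesStatus
from .promoters import PromoterRecord
from .pwm import ALPHABET, PWM

METADATA_COLUMNS = ["species_id", "clade", "trait", "orf_status"]


# -- promoter FASTA ---------------------------------------------------------


def write_promoter_fasta(promoters: Sequence[PromoterRecord], path: str | Path) -> None:
    """Headers are 'species|gene|family'."""
    records = [
        SeqRecord(Seq(p.sequence), id=f"{p.species_id}|{p.gene_id}|{p.family}",
                  description="")
        for p in promoters
    ]
    SeqIO.write(records, str(path), "fasta")


def read_promoter_fasta(path: str | Path) -> list[PromoterRecord]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            species, gene, family = rec.id.split("|")
        except ValueError as exc:
            raise ValueError(
                f"promoter FASTA header {rec.id!r} is not 'species|gene|family'"
            ) from exc
        seq = str(rec.seq).upper()
        out.append(
            PromoterRecord(gene_id=gene, species_id=species, family=family,
                           sequence=seq, requested_length=len(seq),
                           actual_length=len(seq), truncated=False)
        )
    return out


def read_genome_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# -- metadata / truth tables -------------------------------------------------


def write_metadata(statuses: Sequence[SpeciesStatus], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {"species_id": s.species_id, "clade": int(s.clade),
             "trait": int(s.trait), "orf_status": s.orf_status}
            for s in statuses
        ],
        columns=METADATA_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> list[SpeciesStatus]:
    df = pd.read_csv(path, sep="\t")
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"metadata table missing columns: {sorted(missing)}")
    return [
        SpeciesStatus(
            species_id=str(r.species_id), clade=bool(int(r.clade)),
            trait=bool(int(r.trait)), orf_status=str(r.orf_status),
        )
        for r in df.itertuples(index=False)
    ]


# -- trees -------------------------------------------------------------------


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(
        tree.as_string(schema="newick", suppress_rooting=True,
                       unquoted_underscores=True)
    )


def read_tree(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


# -- PWM text ----------------------------------------------------------------


def write_pwm_meme(pwm: PWM, path: str | Path, name: str = "MOTIF_1") -> None:
    """MEME minimal motif format (version line, alphabet, background,
    letter-probability matrix; rows are positions over A C G T)."""
    lines = [
        "MEME version 4",
        "",
        "ALPHABET= ACGT",
        "",
        "Background letter frequencies",
        " ".join(f"{b} {f:.6f}" for b, f in zip(ALPHABET, pwm.background)),
        "",
        f"MOTIF {name}",
        f"letter-probability matrix: alength= 4 w= {pwm.width} nsites= 1 E= 0",
    ]
    for col in pwm.probs.T:
        lines.append(" ".join(f"{x:.6f}" for x in col))
    Path(path).write_text("\n".join(lines) + "\n")


def read_pwm_meme(path: str | Path) -> PWM:
    text = Path(path).read_text().splitlines()
    bg = None
    rows: list[list[float]] = []
    in_matrix = False
    width = None
    for i, line in enumerate(text):
        if line.startswith("Background letter frequencies"):
            parts = text[i + 1].split()
            bg = np.array([float(parts[j]) for j in range(1, 8, 2)])
        elif line.startswith("letter-probability matrix"):
            in_matrix = True
            width = int(line.split("w=")[1].split()[0])
        elif in_matrix and line.strip():
            rows.append([float(x) for x in line.split()])
            if width is not None and len(rows) == width:
                in_matrix = False
    if not rows:
        raise ValueError(f"no letter-probability matrix found in {path}")
    probs = np.asarray(rows).T
    probs = probs / probs.sum(axis=0)  # guard rounding drift
    return PWM(probs, background=bg if bg is not None else np.full(4, 0.25))


def write_pwm_tsv(pwm: PWM, path: str | Path) -> None:
    df = pd.DataFrame(pwm.probs.T, columns=list(ALPHABET))
    df.insert(0, "position", np.arange(1, pwm.width + 1))
    df["information_bits"] = pwm.information_content
    df.to_csv(path, sep="\t", index=False)


# -- gene coordinate table ---------------------------------------------------


def read_gene_table(path: str | Path):
    from .promoters import GeneRecord

    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "species_id", "family", "contig", "strand",
                "translation_start"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"gene table missing columns: {sorted(missing)}")
    genes = []
    for r in df.itertuples(index=False):
        override = getattr(r, "length_override", None)
        if override is not None and pd.isna(override):
            override = None
        genes.append(
            GeneRecord(
                gene_id=str(r.gene_id), species_id=str(r.species_id),
                family=str(r.family), contig=str(r.contig), strand=str(r.strand),
                translation_start=int(r.translation_start),
                length_override=None if override is None else int(override),
            )
        )
    return genes
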
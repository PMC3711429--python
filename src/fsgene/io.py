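"""Readers and writers for the pipeline's plain-text formats.

Genomes and proteins travel as FASTA (via Biopython), tabular data as TSV
(via pandas).  The prediction table dialect has one row per predicted
fs-gene with 0-based half-open coordinates expressed on the coding strand
(for minus-strand genes, on the reverse complement of the genome record).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import FsGene, FsProtein

PREDICTION_COLUMNS = [
    "fs_id", "genome", "strand", "orf1_start", "orf1_end",
    "orf2_start", "orf2_end", "fs_pos", "direction",
    "rbs_score", "genus", "pseudogene_flag",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, sequences: dict[str, str]):
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_predictions(path: str | Path, predictions: pd.DataFrame):
    predictions.to_csv(path, sep="\t", index=False, columns=PREDICTION_COLUMNS)


def read_predictions(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def predictions_to_fs_genes(predictions: pd.DataFrame) -> dict[str, FsGene]:
    """Parse prediction rows into FsGene records, skipping malformed rows."""
    import logging

    logger = logging.getLogger(__name__)
    genes = {}
    for idx, row in predictions.iterrows():
        try:
            gene = FsGene(
                id=str(row["fs_id"]),
                genome_id=str(row["genome"]),
                strand=str(row["strand"]),
                orf1=(int(row["orf1_start"]), int(row["orf1_end"])),
                orf2=(int(row["orf2_start"]), int(row["orf2_end"])),
                fs_pos=int(row["fs_pos"]),
                direction=int(row["direction"]),
                rbs_score=float(row["rbs_score"]),
                genus=str(row.get("genus", "")),
                annotated_pseudogene=bool(int(row.get("pseudogene_flag", 0))),
            )
        except (ValueError, KeyError, TypeError) as exc:
            logger.warning("prediction row %s skipped: %s", idx, exc)
            continue
        genes[gene.id] = gene
    return genes


def write_fs_proteins(path: str | Path, proteins: dict[str, FsProtein]):
    """fs-proteins as FASTA, the frameshift residue encoded in the header."""
    records = [
        SeqRecord(
            Seq(p.aa),
            id=name,
            description=f"fs_aa={p.fs_aa} direction={p.direction:+d}",
        )
        for name, p in proteins.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_domains(path: str | Path) -> dict[str, list[tuple[str, int, int, float]]]:
    frame = pd.read_csv(path, sep="\t")
    out: dict[str, list[tuple[str, int, int, float]]] = {}
    for _, row in frame.iterrows():
        out.setdefault(str(row["protein_id"]), []).append(
            (str(row["domain_name"]), int(row["start"]), int(row["end"]),
             float(row["evalue"]))
        )
    return out


def write_domains(path: str | Path, domains: dict[str, list[tuple[str, int, int, float]]]):
    rows = [
        {"protein_id": pid, "domain_name": d[0], "start": d[1], "end": d[2],
         "evalue": d[3]}
        for pid, ds in domains.items()
        for d in ds
    ]
    pd.DataFrame(
        rows, columns=["protein_id", "domain_name", "start", "end", "evalue"]
    ).to_csv(path, sep="\t", index=False)
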
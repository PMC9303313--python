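"""File-format glue: FASTA via Biopython, tabular inputs/outputs via pandas.

All tables are plain TSV.  Column contracts:

* gapmer TSV: id, sequence, wing5, gap, wing3, backbone, mods
  (semicolon-joined ``CODE@POS`` tokens, may be empty);
* transcript-to-gene TSV: transcript_id, gene_id;
* expression TSV: gene_id, ratio [, control_intensity];
* toxicity TSV: aso_id, ast, alt [, dose, n_animals, flags];
* Tm TSV: aso_id, tm [, source, parent_id].
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from gapmertox.expression import ExpressionTable
from gapmertox.gapmer import GapmerASO, format_gapmer, normalize_sequence, parse_gapmer
from gapmertox.tox import TmRecord, ToxRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_tx2gene",
    "write_tx2gene",
    "read_gapmer_tsv",
    "write_gapmer_tsv",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_tox_tsv",
    "read_tm_tsv",
]

PathLike = Union[str, Path]


def read_fasta(path: PathLike) -> dict[str, str]:
    """Read a (DNA or RNA) FASTA into an ordered id -> sequence dict; U -> T."""
    return {rec.id: normalize_sequence(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: PathLike, sequences: Mapping[str, str]) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_tx2gene(path: PathLike) -> dict[str, str]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if not {"transcript_id", "gene_id"} <= set(frame.columns):
        raise ValueError("tx2gene TSV needs columns transcript_id, gene_id")
    return dict(zip(frame["transcript_id"], frame["gene_id"]))


def write_tx2gene(path: PathLike, tx2gene: Mapping[str, str]) -> None:
    pd.DataFrame(
        {"transcript_id": list(tx2gene), "gene_id": list(tx2gene.values())}
    ).to_csv(path, sep="\t", index=False)


def read_gapmer_tsv(path: PathLike) -> list[GapmerASO]:
    frame = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    asos = []
    for _, row in frame.iterrows():
        asos.append(
            parse_gapmer(
                row["id"],
                row["sequence"],
                wing5_len=int(row.get("wing5", 2) or 2),
                gap_len=int(row["gap"]) if row.get("gap", "") else None,
                wing3_len=int(row.get("wing3", 2) or 2),
                backbone=row.get("backbone", "") or "PS",
                mods=row.get("mods", ""),
            )
        )
    return asos


def write_gapmer_tsv(path: PathLike, asos: Iterable[GapmerASO]) -> None:
    pd.DataFrame([format_gapmer(a) for a in asos]).to_csv(path, sep="\t", index=False)


def read_expression_tsv(path: PathLike, aso_id: str) -> ExpressionTable:
    frame = pd.read_csv(path, sep="\t")
    return ExpressionTable(aso_id=aso_id, data=frame)


def write_expression_tsv(path: PathLike, table: ExpressionTable) -> None:
    table.data.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_tox_tsv(path: PathLike) -> list[ToxRecord]:
    frame = pd.read_csv(path, sep="\t")
    records = []
    for _, row in frame.iterrows():
        records.append(
            ToxRecord(
                aso_id=str(row["aso_id"]),
                ast=float(row["ast"]),
                alt=float(row["alt"]),
                dose=float(row["dose"]) if "dose" in frame.columns else 20.0,
                n_animals=int(row["n_animals"]) if "n_animals" in frame.columns else None,
                flags=tuple(str(row["flags"]).split(";")) if "flags" in frame.columns and pd.notna(row["flags"]) and str(row["flags"]) else (),
            )
        )
    return records


def read_tm_tsv(path: PathLike) -> list[TmRecord]:
    frame = pd.read_csv(path, sep="\t")
    records = []
    for _, row in frame.iterrows():
        parent = row["parent_id"] if "parent_id" in frame.columns and pd.notna(row["parent_id"]) else None
        records.append(
            TmRecord(
                aso_id=str(row["aso_id"]),
                tm=float(row["tm"]),
                source=str(row["source"]) if "source" in frame.columns else "measured",
                parent_id=str(parent) if parent is not None else None,
            )
        )
    return records
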
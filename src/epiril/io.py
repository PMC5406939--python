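"""Readers and writers for the plain-text formats the pipeline exchanges.

All in-memory coordinates are 0-based, half-open. Cytosine reports follow the
Bismark cytosine-report dialect (1-based positions on disk): chrom, pos,
strand, count methylated, count unmethylated, context.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping

import pandas as pd

CYTOSINE_COLUMNS = ["chrom", "pos", "strand", "n_meth", "n_unmeth", "context"]
BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def write_cytosine_report(df: pd.DataFrame, path) -> None:
    out = df[CYTOSINE_COLUMNS].copy()
    out["pos"] = out["pos"] + 1  # 1-based on disk
    out.to_csv(path, sep="\t", header=False, index=False)


def read_cytosine_report(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=CYTOSINE_COLUMNS,
                     dtype={"chrom": str})
    df["pos"] = df["pos"] - 1
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in BED6_COLUMNS if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, dtype={0: str})
    df.columns = BED6_COLUMNS[: df.shape[1]]
    return df


def write_bedgraph(df: pd.DataFrame, path) -> None:
    df[["chrom", "start", "end", "value"]].to_csv(
        path, sep="\t", header=False, index=False)


def read_bedgraph(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None,
                       names=["chrom", "start", "end", "value"],
                       dtype={"chrom": str})


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_config(config, path) -> None:
    """Serialize a simulation config dataclass as ``key = value`` lines."""
    with open(path, "w") as fh:
        for field in dataclasses.fields(config):
            fh.write(f"{field.name} = {getattr(config, field.name)!r}\n")


def read_config(path, cls):
    values = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, raw = line.partition("=")
        values[key.strip()] = eval(raw.strip(), {}, {})  # literals only
    return cls(**values)


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: Mapping[str, str], path, width: int = 70) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in genome.items()]
    seqio_write(records, str(path), "fasta")
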
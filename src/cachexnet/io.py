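"""Readers and writers for the pipeline's plain-text formats."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .normalize import CountMatrix

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_counts(path) -> pd.DataFrame:
    """Counts TSV: feature_id column + one column per sample."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "feature_id"
    return df


def write_counts(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")


def read_sample_sheet(path) -> pd.Series:
    """Sample sheet TSV with columns sample_id, group."""
    df = pd.read_csv(path, sep="\t")
    return pd.Series(df["group"].values, index=df["sample_id"], name="group")


def write_sample_sheet(groups: pd.Series, path) -> None:
    pd.DataFrame(
        {"sample_id": groups.index, "group": groups.values}
    ).to_csv(path, sep="\t", index=False)


def read_count_matrix(
    counts_path, samples_path, lengths_path=None
) -> CountMatrix:
    counts = read_counts(counts_path)
    groups = read_sample_sheet(samples_path)
    lengths = None
    if lengths_path is not None:
        ldf = pd.read_csv(lengths_path, sep="\t", index_col=0)
        lengths = ldf.iloc[:, 0]
    return CountMatrix(counts, groups, lengths)


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = BED_COLUMNS[: df.shape[1]]
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    df[BED_COLUMNS[: df.shape[1]]].to_csv(
        path, sep="\t", header=False, index=False
    )


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
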
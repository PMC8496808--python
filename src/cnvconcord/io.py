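"""File-format helpers: FASTA, BED, TSV, YAML/JSON config and reports.

All tables are tab-separated with a header row; coordinates in BED
output are 0-based half-open.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def write_fasta(records: dict[str, str], path) -> None:
    seqrecs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    SeqIO.write(seqrecs, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into {record id: sequence}; duplicate ids keep the
    first occurrence (callers may warn)."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id not in out:
            out[rec.id] = str(rec.seq).upper()
    return out


def write_bed(intervals: pd.DataFrame, path, chrom: str = "chr1") -> None:
    """Write (name, start, end) rows as BED (0-based, half-open)."""
    df = intervals.copy()
    df.insert(0, "chrom", chrom)
    df[["chrom", "start", "end", df.columns[1]]].to_csv(
        path, sep="\t", header=False, index=False
    )


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def write_yaml(obj, path) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=True))


def read_config(path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)
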
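"""Readers and writers for the plain-text formats used across the pipeline.

Everything on disk is text: FASTA for sequences, TSV for tables, BED6 for
intervals, bedGraph-like TSV for per-base coverage, JSON for the simulation
truth, YAML for configs.  Coordinates are 0-based half-open internally and in
every interval file written here.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{name: sequence}`` dict (uppercased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_tsv(df: pd.DataFrame, path: str | Path, **kwargs) -> None:
    df.to_csv(path, sep="\t", index=False, **kwargs)


def write_bed6(
    intervals: Iterable[tuple[str, int, int, str, float, str]], path: str | Path
) -> None:
    """Write (chrom, start, end, name, score, strand) rows as BED6."""
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score:g}\t{strand}\n")


def read_bed6(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
    )


def write_coverage(cov: Mapping[str, Sequence[float]], path: str | Path) -> None:
    """Write per-base coverage as bedGraph-like rows (run-length compressed)."""
    with open(path, "w") as fh:
        for gene, values in cov.items():
            start = 0
            for i in range(1, len(values) + 1):
                if i == len(values) or values[i] != values[start]:
                    fh.write(f"{gene}\t{start}\t{i}\t{values[start]:g}\n")
                    start = i


def read_coverage(path: str | Path, lengths: Mapping[str, int]) -> dict[str, list[float]]:
    """Expand bedGraph-like rows back to dense per-base arrays.

    ``lengths`` gives the transcript length per gene; uncovered tail positions
    are zero-filled.
    """
    cov = {g: [0.0] * n for g, n in lengths.items()}
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "start", "end", "value"])
    for row in df.itertuples(index=False):
        if row.gene not in cov:
            continue
        arr = cov[row.gene]
        for i in range(row.start, min(row.end, len(arr))):
            arr[i] = float(row.value)
    return cov


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_json_default)


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def _json_default(obj):
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, set):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
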
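"""Format plumbing: FASTA, pair tables, gene-share tables, JSON reports.

Thin wrappers over Biopython/pandas with strict schema validation so that
every artifact round-trips losslessly and malformed inputs fail loudly.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

PAIR_COLUMNS = ["query_id", "ref_id", "ani", "shared_fraction", "n_fragments", "n_bidirectional"]
GENE_SHARE_COLUMNS = ["genome_a", "genome_b", "shared_gene_fraction", "n_orthologs",
                      "n_genes_a", "n_genes_b"]


class SchemaError(ValueError):
    """Raised when a table does not match its documented schema."""


def write_fasta(contigs: dict[str, str], path: str | Path, wrap: int = 80) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in contigs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(records)


def read_fasta(path: str | Path) -> dict[str, str]:
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise SchemaError(f"duplicate contig id {rec.id!r} in {path}")
        contigs[rec.id] = str(rec.seq).upper()
    if not contigs:
        raise SchemaError(f"no FASTA records in {path}")
    return contigs


def write_pair_table(pairs, path: str | Path) -> None:
    """Write AniPair rows; undefined ANI is emitted as NaN."""
    rows = [
        (p.query_id, p.ref_id,
         p.ani if p.ani is not None else math.nan,
         p.shared_fraction, p.n_fragments, p.n_bidirectional)
        for p in pairs
    ]
    pd.DataFrame(rows, columns=PAIR_COLUMNS).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_pair_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PAIR_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"pair table {path} is missing column(s) {missing}")
    bad = df["ani"].dropna()
    if ((bad < 0) | (bad > 100)).any():
        raise SchemaError(f"pair table {path} has ANI values outside [0, 100]")
    return df


def pair_values(df: pd.DataFrame, floor: float = 95.0) -> np.ndarray:
    """Defined ANI values above the distribution floor, as a flat array."""
    vals = df["ani"].to_numpy(dtype=float)
    vals = vals[np.isfinite(vals)]
    return vals[vals > floor]


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
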
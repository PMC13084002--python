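"""Shared table/FASTA readers and writers.

Dialect: UTF-8, mandatory header row, "." decimal, no thousands separators.
TSV for genomic outputs, CSV or TSV accepted on input. Lines starting with
``#`` are metadata comments; every file written by the pipeline carries the
config hash in such a header line.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .expression import MAX_PROMOTER_LEN, PromoterSeq
from .phenotypes import ODCurve


class IOError_(ValueError):
    pass


#: column name -> dtype for each table kind
SCHEMAS = {
    "od": {"time_min": float, "od": float, "strain": str, "replicate": str,
           "treated": bool},
    "traces": {"cell_id": str, "frame": int, "channel": str,
               "nuclear_fraction": float, "median_signal": float},
    "expression": {"gene": str, "strain": str, "timepoint": int,
                   "log2fc": float, "fdr": float},
    "tf_targets": {"tf": str, "target": str},
}


def read_table(path, schema: str | dict) -> pd.DataFrame:
    """Read a CSV/TSV with schema validation and typed columns."""
    path = Path(path)
    if not path.exists():
        raise IOError_(f"no such file: {path}")
    spec = SCHEMAS[schema] if isinstance(schema, str) else schema
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, comment="#")
    if df.empty:
        raise IOError_(f"empty input: {path}")
    missing = [c for c in spec if c not in df.columns]
    if missing:
        raise IOError_(f"{path}: missing required columns {missing}")
    for col, dtype in spec.items():
        try:
            if dtype is float:
                df[col] = pd.to_numeric(df[col], errors="raise")
            elif dtype is int:
                df[col] = df[col].astype(int)
            elif dtype is bool:
                df[col] = df[col].astype(bool)
            else:
                df[col] = df[col].astype(str)
        except (ValueError, TypeError) as e:
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            row = int(bad[0]) if len(bad) else "?"
            raise IOError_(f"{path}: column {col!r} row {row}: {e}") from e
    return df


def write_table(df: pd.DataFrame, path, *, config_hash: str | None = None,
                sep: str | None = None, index: bool = False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    with open(path, "w", encoding="utf-8") as fh:
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, sep=sep, index=index)


def od_curves_from_table(df: pd.DataFrame) -> list[ODCurve]:
    out = []
    for (strain, rep, treated), sub in df.groupby(
        ["strain", "replicate", "treated"], sort=True
    ):
        sub = sub.sort_values("time_min")
        out.append(
            ODCurve(
                times=sub["time_min"].to_numpy(),
                od=sub["od"].to_numpy(),
                strain=strain,
                replicate=rep,
                treated=bool(treated),
            )
        )
    return out


def od_curves_to_table(curves: list[ODCurve]) -> pd.DataFrame:
    rows = []
    for c in curves:
        for t, od in zip(c.times, c.od):
            rows.append({"time_min": t, "od": od, "strain": c.strain,
                         "replicate": c.replicate, "treated": c.treated})
    return pd.DataFrame(rows)


def read_fasta(path) -> list[PromoterSeq]:
    """Read promoter sequences; id is the first header token, sequences are
    uppercased, and records longer than 500 bp are truncated to their
    3'-most 500 bases (the upstream window closest to the start codon)."""
    path = Path(path)
    if not path.exists():
        raise IOError_(f"no such file: {path}")
    out, seen = [], set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise IOError_(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if len(seq) > MAX_PROMOTER_LEN:
            warnings.warn(
                f"{rec.id}: {len(seq)} bp promoter truncated to 3'-most "
                f"{MAX_PROMOTER_LEN} bp",
                stacklevel=2,
            )
            seq = seq[-MAX_PROMOTER_LEN:]
        out.append(PromoterSeq(gene=rec.id, sequence=seq))
    return out


def write_fasta(promoters: list[PromoterSeq], path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for p in promoters:
            fh.write(f">{p.gene}\n")
            for i in range(0, len(p.sequence), 60):
                fh.write(p.sequence[i : i + 60] + "\n")


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable config mapping."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
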
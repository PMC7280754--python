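"""Readers and writers for the plain-text formats the pipeline consumes.

All tables are TSV with a header row; sequences travel as FASTA, gene sets
as GMT.  Readers validate and refuse malformed input with the offending row
or line number in the error message — nothing is silently coerced.  Every
writer/reader pair round-trips exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .core import IsomirRecord, normalize_rna, parse_isomir_coordinate

__all__ = [
    "CountMatrix",
    "GeneSetCollection",
    "read_isomir_table",
    "write_isomir_table",
    "read_fasta",
    "write_fasta",
    "read_gmt",
    "write_gmt",
    "read_count_matrix",
    "write_count_matrix",
    "read_clinical_table",
    "write_clinical_table",
    "read_drug_table",
    "write_drug_table",
    "read_locus_table",
    "write_locus_table",
    "write_edge_list",
    "read_edge_list",
    "write_run_summary",
]

ISOMIR_COLUMNS = ["isomir_id", "locus_id", "arm", "coordinate", "sequence"]


@dataclass
class CountMatrix:
    """A features x samples matrix of nonnegative integer counts.

    ``sample_groups`` maps each sample to its condition (``tumor`` /
    ``normal``); ``pair_id`` optionally links matched tumor/normal samples.
    """

    counts: pd.DataFrame  # index = feature ids, columns = sample ids
    sample_groups: Mapping[str, str]
    pair_id: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        missing = [s for s in self.counts.columns if s not in self.sample_groups]
        if missing:
            raise ValueError(f"samples without a group assignment: {missing[:5]}")
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.counts.columns if self.sample_groups[s] == group]


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style) with free-text descriptions."""

    sets: dict[str, frozenset[str]]
    description: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        empty = [name for name, members in self.sets.items() if not members]
        if empty:
            raise ValueError(f"empty gene sets not allowed: {empty}")


def read_isomir_table(path: str | Path) -> list[IsomirRecord]:
    """Read an isomiR quantification TSV.

    Expected header: isomir_id, locus_id, arm, coordinate, sequence, then one
    column per sample holding nonnegative integer read counts.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ISOMIR_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    sample_cols = [c for c in df.columns if c not in ISOMIR_COLUMNS]
    records = []
    for i, row in df.iterrows():
        rownum = i + 2  # 1-based, counting the header
        try:
            span = parse_isomir_coordinate(row["coordinate"])
            counts = {}
            for s in sample_cols:
                value = int(row[s])
                if value < 0:
                    raise ValueError(f"negative count {value} in sample {s}")
                counts[s] = value
            rec = IsomirRecord(
                isomir_id=row["isomir_id"], locus_id=row["locus_id"], arm=row["arm"],
                span=span, sequence=row["sequence"], counts=counts,
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"{path}: row {rownum}: {exc}") from exc
        records.append(rec)
    return records


def write_isomir_table(records: Sequence[IsomirRecord], path: str | Path) -> None:
    sample_ids = sorted({s for rec in records for s in rec.counts})
    rows = []
    for rec in records:
        row = {
            "isomir_id": rec.isomir_id, "locus_id": rec.locus_id, "arm": rec.arm,
            "coordinate": rec.span.format(), "sequence": rec.sequence,
        }
        row.update({s: rec.counts.get(s, 0) for s in sample_ids})
        rows.append(row)
    pd.DataFrame(rows, columns=ISOMIR_COLUMNS + sample_ids).to_csv(path, sep="\t", index=False)


def read_fasta(path: str | Path, rna: bool = True) -> dict[str, str]:
    """Read FASTA into an id -> sequence map; T is normalized to U for RNA.

    Duplicate ids and empty sequences are rejected.
    """
    out: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in out:
            raise ValueError(f"{path}: duplicate sequence id {record.id!r}")
        seq = str(record.seq).upper()
        if not seq:
            raise ValueError(f"{path}: empty sequence for id {record.id!r}")
        out[record.id] = seq.replace("T", "U") if rna else seq
    return out


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set file: name, description, tab-separated members."""
    sets: dict[str, frozenset[str]] = {}
    description: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >=3 tab-separated fields, got {len(fields)}")
            name, desc, *members = fields
            members = [m for m in members if m]
            if not members:
                raise ValueError(f"{path}: line {lineno}: gene set {name!r} has no members")
            if name in sets:
                raise ValueError(f"{path}: line {lineno}: duplicate set name {name!r}")
            sets[name] = frozenset(members)
            description[name] = desc
    return GeneSetCollection(sets=sets, description=description)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            members = sorted(collection.sets[name])
            desc = collection.description.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_count_matrix(path: str | Path, metadata_path: str | Path) -> CountMatrix:
    """Read a features x samples count TSV plus a sample metadata TSV.

    Metadata columns: sample_id, group, and optionally pair_id.
    """
    counts = pd.read_csv(path, sep="\t", index_col=0)
    if counts.isna().any().any():
        raise ValueError(f"{path}: missing values in count matrix")
    if not np.issubdtype(counts.values.dtype, np.number):
        raise ValueError(f"{path}: non-numeric entries in count matrix")
    counts = counts.astype(np.int64)
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    for col in ("sample_id", "group"):
        if col not in meta.columns:
            raise ValueError(f"{metadata_path}: missing column {col!r}")
    groups = dict(zip(meta["sample_id"], meta["group"]))
    pair = dict(zip(meta["sample_id"], meta["pair_id"])) if "pair_id" in meta.columns else None
    return CountMatrix(counts=counts, sample_groups=groups, pair_id=pair)


def write_count_matrix(matrix: CountMatrix, path: str | Path, metadata_path: str | Path) -> None:
    matrix.counts.to_csv(path, sep="\t", index_label="feature_id")
    rows = {"sample_id": matrix.sample_ids, "group": [matrix.sample_groups[s] for s in matrix.sample_ids]}
    if matrix.pair_id is not None:
        rows["pair_id"] = [matrix.pair_id.get(s, "") for s in matrix.sample_ids]
    pd.DataFrame(rows).to_csv(metadata_path, sep="\t", index=False)


def read_clinical_table(path: str | Path) -> pd.DataFrame:
    """Read a clinical TSV: sample_id, time (positive), event (0/1)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "time", "event"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    if (df["time"] <= 0).any():
        bad = df.index[df["time"] <= 0][0] + 2
        raise ValueError(f"{path}: row {bad}: nonpositive survival time")
    if not df["event"].isin([0, 1]).all():
        bad = df.index[~df["event"].isin([0, 1])][0] + 2
        raise ValueError(f"{path}: row {bad}: event must be 0 or 1")
    return df


def write_clinical_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_drug_table(path: str | Path) -> pd.DataFrame:
    """Read a drug-sensitivity TSV: cell_line, drug, sensitivity in [0,1], isomir_expression."""
    df = pd.read_csv(path, sep="\t")
    for col in ("cell_line", "drug", "sensitivity", "isomir_expression"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    if ((df["sensitivity"] < 0) | (df["sensitivity"] > 1)).any():
        bad = df.index[(df["sensitivity"] < 0) | (df["sensitivity"] > 1)][0] + 2
        raise ValueError(f"{path}: row {bad}: sensitivity outside [0, 1]")
    return df


def write_drug_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


LOCUS_COLUMNS = ["locus_id", "family", "mature_5p_coordinate", "mature_5p_sequence", "pre_sequence"]


def read_locus_table(path: str | Path) -> list:
    """Read a miRNA locus definition TSV (5p-arm loci).

    Columns: locus_id, family, mature_5p_coordinate (span dialect),
    mature_5p_sequence, pre_sequence.
    """
    from .core import MirnaLocus  # local import to avoid a cycle at module load

    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in LOCUS_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    loci = []
    for i, row in df.iterrows():
        try:
            span = parse_isomir_coordinate(row["mature_5p_coordinate"])
            mature = normalize_rna(row["mature_5p_sequence"])
            if len(mature) != span.length:
                raise ValueError(f"mature sequence length {len(mature)} != span length {span.length}")
            loci.append(MirnaLocus(locus_id=row["locus_id"], family=row["family"],
                                   pre_mirna_sequence=normalize_rna(row["pre_sequence"]),
                                   mature_5p=span, annotated_mature_sequences={"5p": mature}))
        except (ValueError, KeyError) as exc:
            raise ValueError(f"{path}: row {i + 2}: {exc}") from exc
    return loci


def write_locus_table(loci, path: str | Path) -> None:
    rows = [
        {"locus_id": lc.locus_id, "family": lc.family,
         "mature_5p_coordinate": lc.mature_5p.format(),
         "mature_5p_sequence": lc.annotated_mature_sequences.get("5p", ""),
         "pre_sequence": lc.pre_mirna_sequence}
        for lc in loci
    ]
    pd.DataFrame(rows, columns=LOCUS_COLUMNS).to_csv(path, sep="\t", index=False)


EDGE_COLUMNS = ["seed_label", "gene_id", "site_type", "gene_sets"]


def write_edge_list(edges: Iterable[Mapping[str, str]], path: str | Path) -> None:
    """Write a bipartite seed -> gene edge list importable by network tools.

    Each edge carries the seed label, gene id, site type and a
    comma-separated list of gene-set annotations; rows are sorted by
    (seed label, gene id) for stable output.
    """
    rows = sorted(edges, key=lambda e: (e["seed_label"], e["gene_id"]))
    df = pd.DataFrame(rows, columns=EDGE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_edge_list(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in EDGE_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return df


def write_run_summary(summary: Mapping, path: str | Path) -> None:
    def _coerce(obj):
        if isinstance(obj, np.integer):
            return int(obj)
        if isinstance(obj, np.floating):
            return float(obj)
        raise TypeError(f"not JSON serializable: {type(obj)}")

    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_coerce)
        fh.write("\n")
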
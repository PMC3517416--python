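"""Readers and writers for the plain-text interchange formats.

All tabular formats are tab-separated with a header row. Numeric columns are
written with fixed precision so that identical inputs produce byte-identical
files.
"""

from __future__ import annotations

import os
from typing import Dict, Iterable, List, Mapping, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

PEAK_COLUMNS = ["sample_id", "mass_da", "migration_min", "amplitude"]

PANEL_COLUMNS = [
    "sequence",
    "protein_name",
    "start",
    "stop",
    "p_adjusted",
    "mean_amp_case",
    "mean_amp_control",
    "regulation",
]


def read_peak_list(path: str | os.PathLike) -> pd.DataFrame:
    """Read a per-sample peak list: sample_id, mass_da, migration_min, amplitude."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in PEAK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"peak list {path} lacks columns: {missing}")
    return df[PEAK_COLUMNS]


def write_peak_list(df: pd.DataFrame, path: str | os.PathLike) -> None:
    out = df[PEAK_COLUMNS].copy()
    out["mass_da"] = out["mass_da"].map(lambda v: f"{v:.4f}")
    out["migration_min"] = out["migration_min"].map(lambda v: f"{v:.3f}")
    out["amplitude"] = out["amplitude"].map(lambda v: f"{v:.2f}")
    out.to_csv(path, sep="\t", index=False)


def read_panel(path: str | os.PathLike) -> pd.DataFrame:
    """Read a sequenced marker panel (Supplementary-style schema).

    An optional ``protein_id`` column is honoured; if absent it defaults to
    ``protein_name`` (the name doubles as the FASTA record id).
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"panel {path} lacks columns: {missing}")
    if "protein_id" not in df.columns:
        df["protein_id"] = df["protein_name"]
    return df


def write_panel(df: pd.DataFrame, path: str | os.PathLike) -> None:
    cols = list(PANEL_COLUMNS)
    if "protein_id" in df.columns:
        cols = cols + ["protein_id"]
    out = df[cols].copy()
    out["p_adjusted"] = out["p_adjusted"].map(lambda v: f"{v:.6g}")
    out["mean_amp_case"] = out["mean_amp_case"].map(lambda v: f"{v:.2f}")
    out["mean_amp_control"] = out["mean_amp_control"].map(lambda v: f"{v:.2f}")
    out.to_csv(path, sep="\t", index=False)


def write_consensus_matrix(peptides, path: str | os.PathLike) -> None:
    """Write consensus peptides as a cluster x sample amplitude matrix.

    Empty cells mean the peptide was not detected in that sample.
    """
    samples = sorted({s for p in peptides for s in p.amplitudes})
    rows = []
    for p in peptides:
        row = {
            "cluster_id": p.cluster_id,
            "mass_da": f"{p.mass:.4f}",
            "migration_min": f"{p.migration_time:.3f}",
        }
        for s in samples:
            amp = p.amplitudes.get(s)
            row[s] = "" if amp is None else f"{amp:.2f}"
        rows.append(row)
    pd.DataFrame(rows, columns=["cluster_id", "mass_da", "migration_min"] + samples).to_csv(
        path, sep="\t", index=False
    )


def read_consensus_matrix(path: str | os.PathLike):
    """Read a consensus matrix back into ConsensusPeptide objects."""
    from .featmatch import ConsensusPeptide

    df = pd.read_csv(path, sep="\t")
    meta = ["cluster_id", "mass_da", "migration_min"]
    samples = [c for c in df.columns if c not in meta]
    peptides = []
    for _, row in df.iterrows():
        amplitudes = {}
        for s in samples:
            v = row[s]
            if pd.notna(v) and v != "":
                amplitudes[s] = float(v)
        peptides.append(
            ConsensusPeptide(
                cluster_id=int(row["cluster_id"]),
                mass=float(row["mass_da"]),
                migration_time=float(row["migration_min"]),
                amplitudes=amplitudes,
            )
        )
    return peptides


def read_fasta(path: str | os.PathLike) -> Dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} mapping."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(proteins: Mapping[str, str], path: str | os.PathLike) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in proteins.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_group_map(path: str | os.PathLike) -> Dict[str, str]:
    """Read sample_id -> group label assignments."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "group"}.issubset(df.columns):
        raise ValueError(f"group map {path} needs columns sample_id, group")
    return dict(zip(df["sample_id"], df["group"]))


def write_group_map(groups: Mapping[str, str], path: str | os.PathLike) -> None:
    pd.DataFrame(
        {"sample_id": list(groups), "group": [groups[s] for s in groups]}
    ).to_csv(path, sep="\t", index=False)


def read_ortholog_map(path: str | os.PathLike) -> List[Tuple[str, str, int]]:
    """Read declared ortholog pairs: rat_id, human_id, optional offset."""
    df = pd.read_csv(path, sep="\t", dtype={"rat_id": str, "human_id": str})
    if not {"rat_id", "human_id"}.issubset(df.columns):
        raise ValueError(f"ortholog map {path} needs columns rat_id, human_id")
    if "offset" not in df.columns:
        df["offset"] = 0
    df["offset"] = df["offset"].fillna(0).astype(int)
    return list(df[["rat_id", "human_id", "offset"]].itertuples(index=False, name=None))


def write_ortholog_map(
    pairs: Iterable[Tuple[str, str, int]], path: str | os.PathLike
) -> None:
    pd.DataFrame(pairs, columns=["rat_id", "human_id", "offset"]).to_csv(
        path, sep="\t", index=False
    )
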
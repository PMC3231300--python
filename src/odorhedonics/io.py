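"""Delimited-text I/O for the small tables this domain works with.

Comma is the default delimiter; tab is accepted (auto-sniffed when
`sep=None`).  No binary formats: profile matrices, vocabularies, molecule
tables and score tables are all plain text with a header row.
"""

from __future__ import annotations

import csv
import hashlib
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

from .chem import MoleculeRecord


def _sniff_sep(path) -> str:
    with open(path, newline="") as fh:
        sample = fh.read(4096)
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
    except csv.Error:
        return ","


def read_profile_matrix(path, sep: Optional[str] = None) -> pd.DataFrame:
    """Odorant x descriptor matrix: first column odorant id, rest descriptors."""
    sep = sep or _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    return df.astype(float)


def read_molecule_table(path, sep: Optional[str] = None) -> list[MoleculeRecord]:
    """Molecule table: columns id, smiles, formula, optional is_acid/is_amine."""
    sep = sep or _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if "id" not in df.columns:
        raise ValueError(f"molecule table {path} needs an 'id' column")
    records = []
    for _, row in df.iterrows():
        flags = {}
        for col, key in (("is_acid", "acid"), ("is_amine", "amine")):
            if col in df.columns and isinstance(row.get(col), str) and row[col].strip():
                flags[key] = row[col].strip().lower() in ("true", "1", "yes")
        smiles = row.get("smiles")
        formula = row.get("formula")
        records.append(
            MoleculeRecord(
                id=str(row["id"]),
                smiles=smiles if isinstance(smiles, str) and smiles.strip() else None,
                formula=formula if isinstance(formula, str) and formula.strip() else None,
                explicit_flags=flags or None,
            )
        )
    return records


def read_scores(path, sep: Optional[str] = None) -> pd.DataFrame:
    sep = sep or _sniff_sep(path)
    df = pd.read_csv(path, sep=sep)
    df["id"] = df["id"].astype(str)
    return df.set_index("id")


def digest_files(paths: Mapping[str, object]) -> dict[str, str]:
    """sha256 digests of the given input files (None entries skipped)."""
    return {
        name: hashlib.sha256(Path(p).read_bytes()).hexdigest()
        for name, p in paths.items()
        if p is not None
    }


def write_table(df: pd.DataFrame, path, sep: str = ",") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=sep)
    return path
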
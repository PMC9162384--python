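"""Delimited-text I/O for regional feature tables, connectivity matrices and results.

All on-disk formats are plain text so that cohorts and results can be diffed,
versioned and regenerated bit-identically:

* regional feature table — TSV, first columns ``subject_id`` and ``group``,
  then one column per atlas region;
* connectivity matrix — whitespace-delimited square matrix, one file per
  subject;
* clinical table — TSV keyed by ``subject_id``;
* NBS results — JSON (components, edges with sign and t, null histogram).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

MATRIX_FMT = "%.10g"


def write_regional_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_regional_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    for col in ("subject_id", "group"):
        if col not in table.columns:
            raise ValueError(f"regional table {path} lacks required column {col!r}")
    region_cols = [c for c in table.columns if c not in ("subject_id", "group")]
    table[region_cols] = table[region_cols].astype(float)
    return table


def write_matrix(matrix: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, np.asarray(matrix), fmt=MATRIX_FMT)


def read_matrix(path: str | Path) -> np.ndarray:
    matrix = np.loadtxt(path)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError(f"{path} is not a square matrix")
    return matrix


def write_clinical_table(clinical: pd.DataFrame, path: str | Path) -> None:
    clinical.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_clinical_table(path: str | Path) -> pd.DataFrame:
    clinical = pd.read_csv(path, sep="\t")
    if "subject_id" not in clinical.columns:
        raise ValueError(f"clinical table {path} lacks required column 'subject_id'")
    return clinical


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def sha256_file(path: str | Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()
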
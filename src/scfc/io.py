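"""File I/O: validated TSV tables and dense text matrices.

Tables (parcellation, cohort, pedigree, phenotypes) are tab-delimited
with a header; connectome matrices are dense whitespace- or
comma-delimited numeric text, one file per subject per measurement with
the filename pattern ``{subject}_{modality}_{measurement}.txt``.  Lines
starting with ``#`` are treated as comments (the pipeline writes a
provenance comment at the top of each output).
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    Connectome,
    FormatError,
    Parcellation,
    Pedigree,
    PhenotypeTable,
    validate_cohort,
)


def _read_tsv(path: str | os.PathLike) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#")
    except (pd.errors.ParserError, ValueError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc


def read_parcellation(path: str | os.PathLike) -> Parcellation:
    """Read a parcellation TSV (region_id, label, hemisphere, network, x, y, z)."""
    t = _read_tsv(path)
    for c in ("x", "y", "z"):
        if c in t.columns and not np.issubdtype(t[c].dtype, np.number):
            raise FormatError(f"non-numeric centroid column {c!r} in {path}")
    return Parcellation(t)


def read_connectome(
    path: str | os.PathLike,
    parcellation: Parcellation,
    modality: str,
    subject_id: str = "",
    measurement_index: int = 1,
) -> Connectome:
    """Read a dense matrix file and validate it against the parcellation."""
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    delim = "," if ("," in lines[0]) else None
    try:
        m = np.array(
            [[float(v) for v in (ln.split(delim))] for ln in lines], dtype=float
        )
    except ValueError as exc:
        raise FormatError(f"non-numeric entry in {path}: {exc}") from exc
    if m.shape != (parcellation.n_regions, parcellation.n_regions):
        raise FormatError(
            f"{path}: matrix is {m.shape}, parcellation has "
            f"{parcellation.n_regions} regions"
        )
    return Connectome(
        matrix=m,
        modality=modality,
        subject_id=subject_id,
        measurement_index=measurement_index,
    )


def write_matrix(matrix: np.ndarray, path: str | os.PathLike, header: str = "") -> None:
    """Write a dense matrix as whitespace-delimited text."""
    np.savetxt(path, np.asarray(matrix, dtype=float), fmt="%.10g", header=header)


def read_pedigree(path: str | os.PathLike) -> Pedigree:
    t = _read_tsv(path)
    for col in ("subject_id", "family_id", "twin_pair_id"):
        if col in t.columns:
            t[col] = t[col].astype("string").fillna("").astype(str)
    return Pedigree(t)


def read_cohort(
    path: str | os.PathLike, required: tuple[str, ...] = ()
) -> pd.DataFrame:
    t = _read_tsv(path)
    if "subject_id" in t.columns:
        t["subject_id"] = t["subject_id"].astype(str)
    return validate_cohort(t, required=required)


def read_phenotypes(path: str | os.PathLike) -> PhenotypeTable:
    t = _read_tsv(path)
    if "subject_id" in t.columns:
        t["subject_id"] = t["subject_id"].astype(str)
    return PhenotypeTable(t)


def write_table(table, path: str | os.PathLike, header: str = "") -> None:
    """Write a table as TSV; accepts DataFrames or the dataclass wrappers.

    ``header``, if given, is written as a leading ``#`` comment line so
    write-then-read round-trips through the readers above.
    """
    df = getattr(table, "table", table)
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        df.to_csv(fh, sep="\t", index=False)


def connectome_filename(subject_id: str, modality: str, measurement_index: int) -> str:
    return f"{subject_id}_{modality}_{measurement_index}.txt"
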
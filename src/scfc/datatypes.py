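"""Core domain types shared by every pipeline stage.

The package works on four kinds of objects: a :class:`Parcellation`
(region metadata: labels, hemisphere, one of nine network assignments,
centroid coordinates), a :class:`Connectome` (a square symmetric
region-by-region matrix, either a structural connectome with
non-negative sparse weights or a functional connectome of Pearson
correlations), a :class:`Pedigree` (family structure with
MZ-twin / DZ-twin / full-sibling / singleton relationship codes) and
validated :class:`pandas.DataFrame` tables for cohort covariates and
region-wise phenotypes.

Validation happens at construction so downstream code can assume the
invariants (unique contiguous region indices, symmetry, modality value
ranges, complete twin pairs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: The nine network labels: the seven canonical cortical resting-state
#: networks plus subcortex and cerebellum/brainstem.
NETWORKS = ("VIS", "SOM", "DATTN", "VATTN", "LIM", "FPN", "DMN", "SUB", "CER/BS")

HEMISPHERES = ("left", "right", "midline")

RELATIONSHIPS = ("MZ_twin", "DZ_twin", "full_sibling", "singleton")

#: Cohort covariate columns used across the analyses.
COHORT_COLUMNS = (
    "age",
    "sex",
    "education",
    "cognition",
    "icv",
    "motion",
    "handedness",
)

#: Absolute tolerance below which matrix asymmetry is treated as
#: round-off and symmetrized away; larger asymmetry is a data error.
SYMMETRY_TOL = 1e-8


class FormatError(ValueError):
    """A file or table violates the expected structure."""


@dataclass(frozen=True)
class Parcellation:
    """Region metadata table.

    ``table`` has columns ``region_id, label, hemisphere, network, x, y, z``
    sorted by ``region_id``; the positional (0-based) order of rows defines
    the region order of every matrix in the pipeline.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = ["region_id", "label", "hemisphere", "network", "x", "y", "z"]
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise FormatError(f"parcellation missing columns: {missing}")
        if t["region_id"].duplicated().any():
            dupes = t.loc[t["region_id"].duplicated(), "region_id"].tolist()
            raise FormatError(f"duplicate region_id values: {dupes}")
        bad_net = set(t["network"]) - set(NETWORKS)
        if bad_net:
            raise FormatError(f"unknown network labels: {sorted(bad_net)}")
        bad_hemi = set(t["hemisphere"]) - set(HEMISPHERES)
        if bad_hemi:
            raise FormatError(f"unknown hemisphere labels: {sorted(bad_hemi)}")
        for c in ("x", "y", "z"):
            if not np.issubdtype(t[c].dtype, np.number):
                raise FormatError(f"non-numeric centroid column {c!r}")
        ordered = t.sort_values("region_id").reset_index(drop=True)
        object.__setattr__(self, "table", ordered)

    @property
    def n_regions(self) -> int:
        return len(self.table)

    @property
    def networks(self) -> np.ndarray:
        """Per-region network label, in region order."""
        return self.table["network"].to_numpy()

    @property
    def hemispheres(self) -> np.ndarray:
        return self.table["hemisphere"].to_numpy()

    @property
    def centroids(self) -> np.ndarray:
        """(n_regions, 3) centroid coordinates in mm."""
        return self.table[["x", "y", "z"]].to_numpy(dtype=float)

    @property
    def labels(self) -> np.ndarray:
        return self.table["label"].to_numpy()

    def network_names(self) -> list[str]:
        """Distinct networks present, in canonical order."""
        present = set(self.table["network"])
        return [n for n in NETWORKS if n in present]


@dataclass(frozen=True)
class Connectome:
    """A square symmetric region-by-region connectivity matrix.

    ``modality`` is ``"SC"`` (non-negative structural weights) or ``"FC"``
    (correlations in [-1, 1]).  The diagonal carries no information and is
    ignored by all downstream computation.
    """

    matrix: np.ndarray
    modality: str
    subject_id: str = ""
    measurement_index: int = 1

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise FormatError(f"connectome matrix must be square, got {m.shape}")
        asym = np.abs(m - m.T).max() if m.size else 0.0
        if asym > SYMMETRY_TOL:
            raise FormatError(
                f"matrix asymmetry {asym:.3g} exceeds tolerance {SYMMETRY_TOL}"
            )
        m = (m + m.T) / 2.0
        if self.modality == "SC":
            if (m < 0).any():
                raise FormatError("SC connectome has negative entries")
        elif self.modality == "FC":
            if np.abs(m).max(initial=0.0) > 1 + 1e-9:
                raise FormatError("FC connectome has entries outside [-1, 1]")
        else:
            raise FormatError(f"unknown modality {self.modality!r}")
        if self.measurement_index < 1:
            raise FormatError("measurement_index must be >= 1")
        m.flags.writeable = False
        object.__setattr__(self, "matrix", m)

    @property
    def n_regions(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class Pedigree:
    """Family structure of the cohort.

    ``table`` columns: ``subject_id, family_id, relationship,
    twin_pair_id`` (the latter empty except for twins).  Members of one
    ``family_id`` are treated as sharing parents; only the four
    relationship classes MZ twin / DZ twin / full sibling / singleton are
    representable.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = ["subject_id", "family_id", "relationship"]
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise FormatError(f"pedigree missing columns: {missing}")
        if "twin_pair_id" not in t.columns:
            t = t.assign(twin_pair_id="")
        t = t.reset_index(drop=True)
        t["twin_pair_id"] = t["twin_pair_id"].fillna("").astype(str)
        if t["subject_id"].duplicated().any():
            raise FormatError("duplicate subject_id in pedigree")
        bad = set(t["relationship"]) - set(RELATIONSHIPS)
        if bad:
            raise FormatError(f"unknown relationship codes: {sorted(bad)}")
        twins = t[t["relationship"].isin(["MZ_twin", "DZ_twin"])]
        for pair_id, grp in twins.groupby("twin_pair_id"):
            if pair_id == "":
                raise FormatError("twin rows require a twin_pair_id")
            if len(grp) != 2:
                raise FormatError(
                    f"twin_pair_id {pair_id!r} has {len(grp)} members, expected 2"
                )
            if grp["family_id"].nunique() != 1:
                raise FormatError(f"twin pair {pair_id!r} spans families")
            if grp["relationship"].nunique() != 1:
                raise FormatError(f"twin pair {pair_id!r} mixes MZ and DZ codes")
        singles = t[t["relationship"] == "singleton"]
        fam_sizes = t.groupby("family_id")["subject_id"].count()
        for fam in singles["family_id"]:
            if fam_sizes[fam] != 1:
                raise FormatError(f"singleton family {fam!r} has other members")
        object.__setattr__(self, "table", t)

    @property
    def n_subjects(self) -> int:
        return len(self.table)

    @property
    def subject_ids(self) -> np.ndarray:
        return self.table["subject_id"].to_numpy()

    @property
    def family_ids(self) -> np.ndarray:
        return self.table["family_id"].to_numpy()

    @property
    def n_families(self) -> int:
        return self.table["family_id"].nunique()


def validate_cohort(table: pd.DataFrame, required: tuple[str, ...] = ()) -> pd.DataFrame:
    """Validate a cohort covariate table (one row per subject).

    ``required`` columns must exist and contain no missing values; the
    error names the offending column so callers can report what a
    requested analysis is missing.
    """
    if "subject_id" not in table.columns:
        raise FormatError("cohort table missing subject_id column")
    if table["subject_id"].duplicated().any():
        raise FormatError("duplicate subject_id in cohort table")
    for col in required:
        if col not in table.columns:
            raise FormatError(f"cohort table missing required column {col!r}")
        if table[col].isna().any():
            raise FormatError(f"cohort column {col!r} has missing values")
    if "sex" in table.columns:
        bad = set(table["sex"].dropna()) - {"female", "male"}
        if bad:
            raise FormatError(f"unknown sex codes: {sorted(bad)}")
    return table


@dataclass(frozen=True)
class PhenotypeTable:
    """Region-wise phenotype measurements, possibly repeated per subject.

    ``table`` has index columns ``subject_id`` and ``measurement_index``
    (1-based within subject) and one numeric column per region.  Used for
    coupling vectors, node strengths and simulated traits; NaN marks an
    undefined value (e.g. a degenerate coupling row).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        for col in ("subject_id", "measurement_index"):
            if col not in t.columns:
                raise FormatError(f"phenotype table missing column {col!r}")
        t = t.reset_index(drop=True)
        if t.duplicated(["subject_id", "measurement_index"]).any():
            raise FormatError("duplicate (subject_id, measurement_index) rows")
        if (t["measurement_index"] < 1).any():
            raise FormatError("measurement_index must be >= 1")
        object.__setattr__(self, "table", t)

    @property
    def region_columns(self) -> list[str]:
        return [
            c for c in self.table.columns
            if c not in ("subject_id", "measurement_index")
        ]

    @property
    def n_regions(self) -> int:
        return len(self.region_columns)

    @property
    def subjects(self) -> np.ndarray:
        """Unique subject ids in first-appearance order."""
        return self.table["subject_id"].unique()

    def measurement_counts(self) -> pd.Series:
        """m_i: number of repeated measures per subject."""
        return self.table.groupby("subject_id", sort=False)["measurement_index"].count()

    def values(self) -> np.ndarray:
        """(n_rows, n_regions) float array in table row order."""
        return self.table[self.region_columns].to_numpy(dtype=float)
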
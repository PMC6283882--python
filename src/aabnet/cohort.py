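"""Cohort tables: validated subjects-by-analytes serology matrices.

A :class:`CohortTable` holds autoantibody concentrations (arbitrary ELISA
units, U/ml) for one or more subject groups together with the metadata the
downstream analyses stratify on (group label, sex, age).  Concentrations are
nonnegative; missing cells are NaN, never 0 — 0 U/ml is a legal concentration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

META_COLUMNS = ("group", "sex", "age")
VALID_SEX = ("female", "male", "unknown")

#: Display labels for the receptor abbreviations used throughout the analyses.
#: Purely cosmetic — no biology is inferred from analyte names.
RECEPTOR_LABELS: dict[str, str] = {
    "AGTR1": "angiotensin II receptor type 1",
    "EDNRA": "endothelin receptor type A",
    "CHRM1": "muscarinic acetylcholine receptor M1",
    "CHRM2": "muscarinic acetylcholine receptor M2",
    "CHRM3": "muscarinic acetylcholine receptor M3",
    "CHRM4": "muscarinic acetylcholine receptor M4",
    "CHRM5": "muscarinic acetylcholine receptor M5",
    "F2R": "protease-activated receptor 1",
    "F2RL1": "protease-activated receptor 2",
    "CXCR3": "C-X-C chemokine receptor 3",
    "CXCR4": "C-X-C chemokine receptor 4",
    "ADRB1": "beta-1 adrenergic receptor",
    "ADRB2": "beta-2 adrenergic receptor",
    "EGFR": "epidermal growth factor receptor",
    "FLT1": "vascular endothelial growth factor receptor 1",
    "KDR": "vascular endothelial growth factor receptor 2",
    "PDGFRB": "platelet-derived growth factor receptor beta",
}


class CohortValidationError(ValueError):
    """Raised when a cohort table violates a structural invariant."""


@dataclass
class CohortTable:
    """Subjects x analytes concentration matrix plus subject metadata.

    Parameters
    ----------
    meta:
        DataFrame indexed by subject_id with columns ``group``, ``sex``,
        ``age``.  ``sex`` is one of {female, male, unknown}; ``age`` is years
        (NaN allowed).
    values:
        DataFrame indexed by subject_id (same index as ``meta``), one column
        per analyte, values >= 0 or NaN.
    """

    meta: pd.DataFrame
    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.meta = self.meta.copy()
        self.values = self.values.copy()
        validate_cohort_table(self)

    # -- conveniences -----------------------------------------------------
    @property
    def subject_ids(self) -> pd.Index:
        return self.values.index

    @property
    def analytes(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_subjects(self) -> int:
        return len(self.values)

    @property
    def groups(self) -> list[str]:
        return sorted(self.meta["group"].dropna().unique().tolist())

    def select_groups(self, groups: Sequence[str]) -> "CohortTable":
        mask = self.meta["group"].isin(list(groups))
        return CohortTable(self.meta.loc[mask], self.values.loc[mask])

    def subset(self, subject_ids: Sequence) -> "CohortTable":
        ids = pd.Index(subject_ids)
        return CohortTable(self.meta.loc[ids], self.values.loc[ids])

    def group_values(self, group: str, analyte: str | None = None):
        """Concentration matrix (or one analyte's vector) for one group."""
        mask = self.meta["group"] == group
        sub = self.values.loc[mask]
        return sub if analyte is None else sub[analyte]


def validate_cohort_table(table: CohortTable) -> None:
    meta, values = table.meta, table.values
    if not meta.index.equals(values.index):
        raise CohortValidationError("meta and values must share the subject index")
    if meta.index.has_duplicates:
        dups = meta.index[meta.index.duplicated()].unique().tolist()
        raise CohortValidationError(f"duplicate subject_id(s): {dups}")
    if values.columns.has_duplicates:
        dups = values.columns[values.columns.duplicated()].unique().tolist()
        raise CohortValidationError(f"duplicate analyte name(s): {dups}")
    missing_meta = [c for c in META_COLUMNS if c not in meta.columns]
    if missing_meta:
        raise CohortValidationError(f"missing metadata column(s): {missing_meta}")
    bad_sex = set(meta["sex"].dropna().unique()) - set(VALID_SEX)
    if bad_sex:
        raise CohortValidationError(f"invalid sex value(s): {sorted(bad_sex)}")
    age = pd.to_numeric(meta["age"], errors="coerce")
    if (age.dropna() < 0).any():
        bad = meta.index[age < 0].tolist()
        raise CohortValidationError(f"negative age for subject(s): {bad}")
    arr = values.to_numpy(dtype=float)
    neg = np.asarray(arr < 0) & np.isfinite(arr)
    if neg.any():
        i, j = map(int, np.argwhere(neg)[0])
        raise CohortValidationError(
            f"negative concentration at subject {values.index[i]!r}, "
            f"analyte {values.columns[j]!r}: {arr[i, j]}"
        )


# ---------------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------------

DEFAULT_SCHEMA = {"subject_id": "subject_id", "group": "group", "sex": "sex", "age": "age"}

_NA_VALUES = ["", "NA", "NaN", "nan"]


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_cohort_table(
    path: str | Path, schema: Mapping[str, str] | None = None
) -> CohortTable:
    """Read a delimited cohort file (CSV/TSV chosen by extension).

    ``schema`` maps the canonical column roles (subject_id, group, sex, age)
    to the column names actually present in the file; every remaining column
    is treated as an analyte.  Empty cells and "NA" are missing.
    """
    path = Path(path)
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    df = pd.read_csv(path, sep=_sep_for(path), na_values=_NA_VALUES, keep_default_na=False)
    for role, col in schema.items():
        if col not in df.columns:
            raise CohortValidationError(
                f"column {col!r} (role {role!r}) not found in {path.name}"
            )
    meta = df[[schema["group"], schema["sex"], schema["age"]]].copy()
    meta.columns = ["group", "sex", "age"]
    meta["age"] = pd.to_numeric(meta["age"], errors="coerce")
    meta.index = pd.Index(df[schema["subject_id"]].astype(str), name="subject_id")
    analyte_cols = [c for c in df.columns if c not in set(schema.values())]
    values = df[analyte_cols].apply(pd.to_numeric, errors="coerce")
    values.index = meta.index
    table = CohortTable(meta, values)
    logger.info(
        "read %s: %d subjects x %d analytes", path.name, table.n_subjects, len(analyte_cols)
    )
    return table


def write_cohort_table(table: CohortTable, path: str | Path) -> Path:
    """Write a cohort table to CSV/TSV (missing cells written as empty)."""
    path = Path(path)
    out = pd.concat([table.meta, table.values], axis=1)
    out.insert(0, "subject_id", out.index)
    out.to_csv(path, sep=_sep_for(path), index=False, na_rep="")
    return path


# ---------------------------------------------------------------------------
# Stratification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StratumSpec:
    """How to split a cohort: by ``group``, ``sex``, or the 65-year ``age65``
    dichotomy (age < cut -> "young", age >= cut -> "older")."""

    by: str  # one of {"group", "sex", "age65"}
    age_cut: float = 65.0

    def __post_init__(self) -> None:
        if self.by not in {"group", "sex", "age65"}:
            raise ValueError(f"unknown stratification variable: {self.by!r}")


@dataclass
class Stratification:
    """Partition of a cohort into strata plus the excluded subjects
    (those with a missing stratum variable)."""

    strata: list[tuple[str, CohortTable]]
    excluded: CohortTable
    spec: StratumSpec = field(default=None)  # type: ignore[assignment]

    def __iter__(self) -> Iterator[tuple[str, CohortTable]]:
        return iter(self.strata)

    def __len__(self) -> int:
        return len(self.strata)

    @property
    def n_excluded(self) -> int:
        return self.excluded.n_subjects

    def labels(self) -> list[str]:
        return [label for label, _ in self.strata]


def stratify(table: CohortTable, spec: StratumSpec) -> Stratification:
    """Partition subjects by the stratum variable.

    Subjects with a missing stratum variable are excluded (and returned in
    ``.excluded``); the union of strata plus excluded equals the original
    table.  Empty strata are kept (with a warning) so that the label set is
    stable across cohorts.
    """
    if spec.by == "age65":
        age = pd.to_numeric(table.meta["age"], errors="coerce")
        missing = age.isna()
        labels = pd.Series(
            np.where(age < spec.age_cut, "young", "older"), index=table.meta.index
        )
        expected = ["young", "older"]
    else:
        var = table.meta[spec.by]
        missing = var.isna()
        labels = var.astype("string")
        expected = sorted(labels.dropna().unique().tolist())
        if spec.by == "sex":
            expected = [s for s in ("female", "male", "unknown") if s in set(expected)] or list(VALID_SEX[:2])

    strata: list[tuple[str, CohortTable]] = []
    for label in expected:
        ids = table.meta.index[(labels == label) & ~missing]
        sub = table.subset(ids)
        if sub.n_subjects == 0:
            logger.warning("stratum %r is empty", label)
        strata.append((label, sub))
    excluded = table.subset(table.meta.index[missing])
    if excluded.n_subjects:
        logger.info("%d subject(s) excluded: missing %s", excluded.n_subjects, spec.by)
    return Stratification(strata=strata, excluded=excluded, spec=spec)
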
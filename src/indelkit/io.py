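"""Cohort and qPCR table I/O.

Cohort tables are plain delimited text (CSV/TSV autodetected by extension)
with one row per animal: an animal id, a herd-year-season (HYS) label, one
genotype column per indel locus coded ``II``/``ID``/``DD``, and a first-born
litter size.  Genotypes are unphased gel-electrophoresis calls, so ``DI``
normalises to ``ID``.  Missing values are the empty string or ``NA``.

qPCR Ct tables come in long form (``sample_id, gene, ct, group``) or wide
form (samples x genes with a ``group`` column).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GENOTYPES = ("II", "ID", "DD")
_MISSING_STRINGS = {"", "NA", "NAN", "NONE", "."}


class FormatError(ValueError):
    """A table does not have the columns or dialect the schema requires."""


class ValidationError(ValueError):
    """A table parses but violates an invariant (e.g. duplicate ids)."""


@dataclass(frozen=True)
class IndelLocus:
    """A biallelic insertion/deletion locus genotyped as II/ID/DD."""

    locus_id: str
    allele_ins_label: str = "I"
    allele_del_label: str = "D"
    description: str = ""


@dataclass(frozen=True)
class GenotypeCounts:
    """Observed genotype counts at one biallelic indel locus."""

    n_II: int
    n_ID: int
    n_DD: int

    def __post_init__(self) -> None:
        for name in ("n_II", "n_ID", "n_DD"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")

    @property
    def n_total(self) -> int:
        return self.n_II + self.n_ID + self.n_DD

    def as_array(self) -> np.ndarray:
        return np.array([self.n_II, self.n_ID, self.n_DD], dtype=float)


@dataclass
class CohortTable:
    """Per-animal records: genotypes per locus, HYS label, litter size.

    ``data`` holds columns ``animal_id``, ``hys``, ``litter_size`` (nullable
    integer) and one string column per locus id.  ``loci`` lists the locus
    columns in declared order; ``warnings`` counts genotype strings that
    could not be interpreted and were set to missing.
    """

    data: pd.DataFrame
    loci: list[str]
    warnings: int = 0

    def __len__(self) -> int:
        return len(self.data)

    @property
    def has_litter_size(self) -> bool:
        return self.data["litter_size"].notna().any()


def normalize_genotype(value: object) -> str | None:
    """Map a raw genotype string onto {II, ID, DD} or None.

    Unordered pair labels: ``DI`` becomes ``ID``.  Anything outside the
    declared code set is None (missing).
    """
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    code = str(value).strip().upper()
    if code in _MISSING_STRINGS:
        return None
    if code == "DI":
        code = "ID"
    return code if code in GENOTYPES else "?"


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_cohort(
    path: str | Path,
    schema: Mapping[str, object] | None = None,
    require_litter_size: bool = False,
) -> CohortTable:
    """Read and validate a delimited cohort table.

    ``schema`` maps roles to column names: ``animal_id``, ``hys``,
    ``litter_size`` (each a column name) and ``loci`` (list of genotype
    column names).  Defaults assume columns of those exact names, with every
    unclaimed column treated as a locus.  Unknown genotype strings become
    missing; the count is recorded on the returned table and logged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    schema = dict(schema or {})
    id_col = schema.get("animal_id", "animal_id")
    hys_col = schema.get("hys", "hys")
    ls_col = schema.get("litter_size", "litter_size")

    if id_col not in raw.columns:
        raise FormatError(f"missing mandatory column {id_col!r} in {path}")
    if hys_col not in raw.columns:
        raise FormatError(f"missing mandatory column {hys_col!r} in {path}")
    if ls_col not in raw.columns:
        if require_litter_size:
            raise FormatError(
                f"litter-size column {ls_col!r} absent but required in {path}"
            )
        raw[ls_col] = pd.NA

    loci = list(schema.get("loci") or [c for c in raw.columns
                                       if c not in {id_col, hys_col, ls_col}])
    missing_loci = [c for c in loci if c not in raw.columns]
    if missing_loci:
        raise FormatError(f"locus columns absent: {missing_loci}")

    if raw[id_col].duplicated().any():
        dupes = raw[id_col][raw[id_col].duplicated()].unique()[:5]
        raise ValidationError(f"duplicate animal_id values: {list(dupes)}")

    out = pd.DataFrame({
        "animal_id": raw[id_col].astype(str),
        "hys": raw[hys_col].fillna("NA").astype(str),
    })
    ls = pd.to_numeric(raw[ls_col].replace(list(_MISSING_STRINGS), pd.NA),
                       errors="coerce")
    if (ls.dropna() < 1).any():
        raise ValidationError("litter_size must be >= 1 when present")
    out["litter_size"] = ls.astype("Int64")

    n_bad = 0
    for locus in loci:
        codes = raw[locus].map(normalize_genotype)
        n_bad += int((codes == "?").sum())
        out[locus] = codes.replace("?", None)
    if n_bad:
        logger.warning("%d unrecognised genotype codes set to missing", n_bad)
    return CohortTable(data=out, loci=loci, warnings=n_bad)


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    """Write a cohort table back to CSV/TSV (dialect by extension)."""
    path = Path(path)
    cols = ["animal_id", "hys", "litter_size"] + cohort.loci
    cohort.data[cols].to_csv(path, sep=_sep_for(path), index=False)


def count_genotypes(cohort: CohortTable, locus: IndelLocus | str) -> GenotypeCounts:
    """Tally II/ID/DD at one locus, excluding missing genotypes."""
    locus_id = locus.locus_id if isinstance(locus, IndelLocus) else locus
    if locus_id not in cohort.loci:
        raise KeyError(f"locus {locus_id!r} not in cohort (has {cohort.loci})")
    col = cohort.data[locus_id]
    return GenotypeCounts(
        n_II=int((col == "II").sum()),
        n_ID=int((col == "ID").sum()),
        n_DD=int((col == "DD").sum()),
    )


@dataclass
class CtMatrix:
    """qPCR Ct values, samples x genes, with per-sample group labels.

    ``roles`` optionally flags genes as ``target`` or ``candidate-reference``.
    """

    ct: pd.DataFrame                      # index: sample_id, columns: genes
    groups: pd.Series                     # index: sample_id -> group label
    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.ct.to_numpy(dtype=float) < 0).any():
            raise ValidationError("negative Ct values")
        if not self.ct.index.equals(self.groups.index):
            self.groups = self.groups.reindex(self.ct.index)
        if self.groups.isna().any():
            raise ValidationError("every sample needs a group label")

    @property
    def genes(self) -> list[str]:
        return list(self.ct.columns)


def read_ct(path: str | Path, schema: Mapping[str, str] | None = None) -> CtMatrix:
    """Read a Ct table, long (sample_id, gene, ct, group) or wide form.

    Wide form is detected when no ``gene``/``ct`` columns are present; then
    every column other than the sample id and group is a gene.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    schema = dict(schema or {})
    sample_col = schema.get("sample_id", "sample_id")
    group_col = schema.get("group", "group")
    gene_col = schema.get("gene", "gene")
    ct_col = schema.get("ct", "ct")

    raw = pd.read_csv(path, sep=_sep_for(path))
    if sample_col not in raw.columns or group_col not in raw.columns:
        raise FormatError(f"Ct table needs {sample_col!r} and {group_col!r} columns")
    if gene_col in raw.columns and ct_col in raw.columns:
        wide = raw.pivot_table(index=sample_col, columns=gene_col,
                               values=ct_col, aggfunc="mean")
        groups = raw.drop_duplicates(sample_col).set_index(sample_col)[group_col]
        return CtMatrix(ct=wide, groups=groups.reindex(wide.index))
    genes = [c for c in raw.columns if c not in {sample_col, group_col}]
    if not genes:
        raise FormatError("no gene columns found in wide-form Ct table")
    wide = raw.set_index(sample_col)[genes].astype(float)
    return CtMatrix(ct=wide, groups=raw.set_index(sample_col)[group_col])


def write_ct(ct: CtMatrix, path: str | Path) -> None:
    """Write a Ct matrix in wide form."""
    path = Path(path)
    out = ct.ct.copy()
    out.insert(0, "group", ct.groups)
    out.to_csv(path, sep=_sep_for(path), index_label="sample_id")


def cohort_from_records(
    records: Iterable[Mapping[str, object]], loci: Sequence[str]
) -> CohortTable:
    """Build a CohortTable from in-memory records (used by simulators)."""
    df = pd.DataFrame.from_records(list(records))
    df["litter_size"] = pd.array(df.get("litter_size"), dtype="Int64")
    df["hys"] = df.get("hys", "HYS1")
    return CohortTable(data=df, loci=list(loci))
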
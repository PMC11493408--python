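"""Domain types and harmonized TSV input/output for line-panel phenotype data.

A *line* is one inbred, near-homozygous genotype (e.g. a DGRP line); phenotypes
are measured per line and per sex.  Data exchange follows the community
guidelines for panel phenotyping files: a matrix with line identifiers in the
first column, sex (M/F/NA) in the second, one column per phenotype, a header
row, and a single NA convention.  Phenotype metadata (name, unit, declared
dtype, sex) travels in a companion table rather than being inferred from the
values.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import (
    LookupError_,
    MalformedIdentifierError,
    TableFormatError,
)

SEX_CODES = ("M", "F", "NA")
CURATION_STATUSES = ("submitted", "under_curation", "curated")

_LINE_RE = re.compile(r"^DGRP_(\d{3})$")
_DIGITS_RE = re.compile(r"(\d+)")

#: NA spellings accepted on input; output always uses a single token.
NA_TOKENS = ("NA", "")
DEFAULT_NA_TOKEN = "NA"


# ---------------------------------------------------------------------------
# line identifiers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LineID:
    """A panel line identifier with its original spelling retained.

    ``canonical`` always has the form ``DGRP_XXX`` with a zero-padded
    three-digit line number; ``raw_label`` preserves the input for provenance.
    """

    raw_label: str
    canonical: str

    def __post_init__(self) -> None:
        if not _LINE_RE.match(self.canonical):
            raise MalformedIdentifierError(
                f"not a canonical line ID: {self.canonical!r}"
            )

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.canonical


def normalize_line_id(raw: str | LineID) -> LineID:
    """Canonicalize a line label to ``DGRP_XXX`` (zero-padded, 3 digits).

    Accepts the common spellings found in published tables ("DGRP-42",
    "line_21", "RAL_757", "ral757", plain "42", ...): the line number is the
    first run of digits in the label.  Numbers above 999 are rejected — all
    published DGRP line numbers fit in three digits.

    Idempotent: normalizing an already-canonical ID returns it unchanged.
    """
    if isinstance(raw, LineID):
        return raw
    label = str(raw).strip()
    m = _DIGITS_RE.search(label)
    if m is None:
        raise MalformedIdentifierError(
            f"no line number found in identifier {label!r}"
        )
    number = int(m.group(1))
    if number > 999:
        raise MalformedIdentifierError(
            f"line number {number} out of range (max 999) in {label!r}"
        )
    return LineID(raw_label=label, canonical=f"DGRP_{number:03d}")


def normalize_sex(code: str) -> str:
    """Map a sex cell to one of M / F / NA (tolerant input, strict output)."""
    c = str(code).strip().upper()
    if c in ("", "NAN", "NONE"):
        return "NA"
    if c not in SEX_CODES:
        raise TableFormatError(f"invalid sex code {code!r}; expected M, F or NA")
    return c


# ---------------------------------------------------------------------------
# descriptors, tables, registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhenotypeDescriptor:
    """Metadata for one sex-specific phenotype column of one study."""

    study_id: str
    phenotype_id: str
    name: str
    sex: str
    unit: str = ""
    dtype: str = "quantitative"  # or "categorical"
    is_summary: bool = True

    def __post_init__(self) -> None:
        if self.sex not in SEX_CODES:
            raise TableFormatError(f"invalid sex {self.sex!r} in descriptor")
        if self.dtype not in ("quantitative", "categorical"):
            raise TableFormatError(f"invalid dtype {self.dtype!r} in descriptor")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.study_id, self.phenotype_id, self.sex)

    @property
    def label(self) -> str:
        return f"{self.study_id}:{self.phenotype_id}:{self.sex}"


@dataclass(frozen=True)
class StudyMeta:
    study_id: str
    title: str = ""
    categories: tuple[str, ...] = ()
    status: str = "submitted"

    def __post_init__(self) -> None:
        if self.status not in CURATION_STATUSES:
            raise TableFormatError(f"invalid curation status {self.status!r}")


@dataclass
class PhenotypeTable:
    """One study's line × phenotype value matrix.

    ``data`` holds one row per (line, sex): a ``line_id`` column of canonical
    identifiers, a ``sex`` column, then one float column per phenotype.
    Missing measurements are ``NaN``.
    """

    study_id: str
    data: pd.DataFrame
    warnings: list[str] = field(default_factory=list, compare=False)

    def __post_init__(self) -> None:
        cols = list(self.data.columns)
        if cols[:2] != ["line_id", "sex"]:
            raise TableFormatError(
                f"table for {self.study_id!r} must start with line_id, sex columns"
            )
        dup = self.data.duplicated(subset=["line_id", "sex"])
        if dup.any():
            where = self.data.loc[dup, "line_id"].tolist()
            raise TableFormatError(
                f"duplicated (line, sex) rows in study {self.study_id!r}: {where}"
            )

    @property
    def phenotype_ids(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("line_id", "sex")]

    @property
    def lines(self) -> list[str]:
        return list(self.data["line_id"])

    def values_for(self, phenotype_id: str, sex: str) -> pd.Series:
        """Per-line values of one phenotype for one sex, indexed by line ID."""
        if phenotype_id not in self.phenotype_ids:
            raise LookupError_(
                f"phenotype {phenotype_id!r} not in study {self.study_id!r}"
            )
        sub = self.data[self.data["sex"] == sex]
        return pd.Series(
            sub[phenotype_id].to_numpy(), index=list(sub["line_id"]), name=phenotype_id
        )


@dataclass
class PhenotypeRegistry:
    """Studies, their phenotype descriptors and their value tables.

    The join surface for every analysis: descriptors are addressed by
    (study_id, phenotype_id, sex) and resolve to per-line value series.
    """

    studies: dict[str, StudyMeta] = field(default_factory=dict)
    descriptors: list[PhenotypeDescriptor] = field(default_factory=list)
    tables: dict[str, PhenotypeTable] = field(default_factory=dict)

    def add_study(self, meta: StudyMeta, table: PhenotypeTable,
                  descriptors: list[PhenotypeDescriptor]) -> None:
        if meta.study_id in self.studies:
            raise TableFormatError(f"duplicate study {meta.study_id!r}")
        if table.study_id != meta.study_id:
            raise TableFormatError("table/study ID mismatch")
        self.studies[meta.study_id] = meta
        self.tables[meta.study_id] = table
        self.descriptors.extend(descriptors)

    def descriptor(self, study_id: str, phenotype_id: str, sex: str) -> PhenotypeDescriptor:
        for d in self.descriptors:
            if d.key == (study_id, phenotype_id, sex):
                return d
        raise LookupError_(f"no descriptor {study_id}:{phenotype_id}:{sex}")

    def series(self, desc: PhenotypeDescriptor) -> pd.Series:
        """Per-line values behind a descriptor (NaN for missing lines kept)."""
        if desc.study_id not in self.tables:
            raise LookupError_(f"no table for study {desc.study_id!r}")
        return self.tables[desc.study_id].values_for(desc.phenotype_id, desc.sex)

    def select_descriptors(self, *, scope: str = "all", sexes=None,
                           dtype: str | None = None,
                           categories=None) -> list[PhenotypeDescriptor]:
        """Descriptors filtered by curation scope, sex, dtype and categories.

        ``scope`` is ``"curated_only"`` or ``"all"``; category matching is
        case-insensitive and exact at the study level.
        """
        if scope not in ("all", "curated_only"):
            raise TableFormatError(f"invalid scope {scope!r}")
        cats = {c.strip().lower() for c in categories} if categories else None
        out = []
        for d in sorted(self.descriptors, key=lambda d: d.key):
            study = self.studies.get(d.study_id)
            if study is None:
                continue
            if scope == "curated_only" and study.status != "curated":
                continue
            if sexes is not None and d.sex not in sexes:
                continue
            if dtype is not None and d.dtype != dtype:
                continue
            if cats is not None and not (
                {c.lower() for c in study.categories} & cats
            ):
                continue
            out.append(d)
        return out


# ---------------------------------------------------------------------------
# TSV/CSV I/O
# ---------------------------------------------------------------------------

def _sniff_delimiter(header: str) -> str:
    if "\t" in header:
        return "\t"
    if "," in header:
        return ","
    raise TableFormatError(
        "could not detect a tab or comma delimiter in the header row"
    )


def read_phenotype_table(path: str | Path, study_id: str | None = None,
                         dtypes: dict[str, str] | None = None) -> PhenotypeTable:
    """Read a guideline-format phenotype matrix (TSV or CSV).

    Layout: line IDs first, sex second, phenotypes after, with a header row.
    "NA" and empty cells both mean missing; if a file mixes the two
    conventions a warning is recorded on the returned table (single-convention
    files are clean).  Columns declared categorical in ``dtypes`` are kept as
    strings; everything else must parse as numbers.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
    sep = _sniff_delimiter(header)
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if raw.shape[1] < 2:
        raise TableFormatError(f"{path.name}: need at least line and sex columns")

    warnings: list[str] = []
    cols = list(raw.columns)
    sex_raw = raw[cols[1]].astype(str)
    sex_like = sex_raw.str.strip().str.upper().isin(SEX_CODES + ("",))
    if not sex_like.all():
        raise TableFormatError(
            f"{path.name}: second column {cols[1]!r} is not a sex column "
            "(expected M/F/NA); the guideline format puts line IDs first and "
            "sex second, before all phenotypes"
        )

    na_seen = set()
    pheno_cols = cols[2:]
    for c in pheno_cols:
        vals = raw[c].str.strip()
        na_seen.update(t for t in NA_TOKENS if (vals == t).any())
    if len(na_seen) > 1:
        warnings.append(
            "mixed NA conventions: both 'NA' and empty cells present; "
            "unified to missing"
        )

    data = {
        "line_id": [normalize_line_id(v).canonical for v in raw[cols[0]]],
        "sex": [normalize_sex(v) for v in sex_raw],
    }
    dtypes = dtypes or {}
    for c in pheno_cols:
        vals = raw[c].str.strip().replace(list(NA_TOKENS), np.nan)
        if dtypes.get(c) == "categorical":
            data[c] = vals
            continue
        parsed = pd.to_numeric(vals, errors="coerce")
        bad = parsed.isna() & vals.notna()
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise TableFormatError(
                f"{path.name}: non-numeric value {vals.iloc[i]!r} in quantitative "
                f"column {c!r}, data row {i + 1}"
            )
        data[c] = parsed.astype(float)
    table = PhenotypeTable(
        study_id=study_id or path.stem,
        data=pd.DataFrame(data),
    )
    table.warnings = warnings
    return table


def write_phenotype_table(table: PhenotypeTable, path: str | Path,
                          na_token: str = DEFAULT_NA_TOKEN) -> Path:
    """Write a table in the guideline TSV layout with a single NA token."""
    path = Path(path)
    table.data.to_csv(path, sep="\t", index=False, na_rep=na_token)
    return path


# registry directory layout: studies.tsv + phenotypes.tsv + one table per study
_STUDIES_FILE = "studies.tsv"
_DESCRIPTORS_FILE = "phenotypes.tsv"


def write_registry(reg: PhenotypeRegistry, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    studies = pd.DataFrame(
        [
            {
                "study_id": s.study_id,
                "title": s.title,
                "categories": ";".join(s.categories),
                "status": s.status,
            }
            for s in reg.studies.values()
        ]
    )
    studies.to_csv(directory / _STUDIES_FILE, sep="\t", index=False)
    desc = pd.DataFrame(
        [
            {
                "study_id": d.study_id,
                "phenotype_id": d.phenotype_id,
                "name": d.name,
                "sex": d.sex,
                "unit": d.unit,
                "dtype": d.dtype,
                "is_summary": int(d.is_summary),
            }
            for d in reg.descriptors
        ]
    )
    desc.to_csv(directory / _DESCRIPTORS_FILE, sep="\t", index=False)
    for study_id, table in reg.tables.items():
        write_phenotype_table(table, directory / f"pheno_{study_id}.tsv")
    return directory


def read_registry(directory: str | Path) -> PhenotypeRegistry:
    directory = Path(directory)
    studies_path = directory / _STUDIES_FILE
    if not studies_path.exists():
        raise TableFormatError(f"no {_STUDIES_FILE} in {directory}")
    studies_df = pd.read_csv(studies_path, sep="\t", dtype=str, keep_default_na=False)
    desc_df = pd.read_csv(
        directory / _DESCRIPTORS_FILE, sep="\t", dtype=str, keep_default_na=False
    )
    reg = PhenotypeRegistry()
    for _, row in studies_df.iterrows():
        sid = row["study_id"]
        meta = StudyMeta(
            study_id=sid,
            title=row.get("title", ""),
            categories=tuple(c for c in row.get("categories", "").split(";") if c),
            status=row.get("status", "submitted") or "submitted",
        )
        sub = desc_df[desc_df["study_id"] == sid]
        descriptors = [
            PhenotypeDescriptor(
                study_id=sid,
                phenotype_id=r["phenotype_id"],
                name=r["name"],
                sex=r["sex"],
                unit=r["unit"],
                dtype=r["dtype"],
                is_summary=bool(int(r["is_summary"])),
            )
            for _, r in sub.iterrows()
        ]
        dtypes = {r["phenotype_id"]: r["dtype"] for _, r in sub.iterrows()}
        table = read_phenotype_table(
            directory / f"pheno_{sid}.tsv", study_id=sid, dtypes=dtypes
        )
        reg.add_study(meta, table, descriptors)
    return reg


def read_metadata_yaml(path: str | Path) -> list[PhenotypeDescriptor]:
    """Read a companion YAML metadata file (one entry per phenotype)."""
    with open(path, encoding="utf-8") as fh:
        entries = yaml.safe_load(fh) or []
    return [
        PhenotypeDescriptor(
            study_id=e["study_id"],
            phenotype_id=e["phenotype_id"],
            name=e.get("name", e["phenotype_id"]),
            sex=normalize_sex(e.get("sex", "NA")),
            unit=str(e.get("unit", "")),
            dtype=e.get("dtype", "quantitative"),
            is_summary=bool(e.get("is_summary", True)),
        )
        for e in entries
    ]


# ---------------------------------------------------------------------------
# validation and summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Violation:
    code: str  # malformed_id | duplicate_row | missing_unit | missing_column | bad_reference
    location: str
    message: str


def validate_registry(reg: PhenotypeRegistry) -> list[Violation]:
    """Check a registry against the data-sharing guidelines.

    Returns one violation per problem (malformed line IDs, duplicated
    (line, sex) rows, unitless quantitative phenotypes, descriptors pointing
    at missing studies/columns); an empty report means the registry is clean.
    """
    report: list[Violation] = []
    for study_id, table in reg.tables.items():
        for i, lid in enumerate(table.data["line_id"]):
            if not _LINE_RE.match(str(lid)):
                report.append(Violation(
                    "malformed_id", f"{study_id}:row{i}",
                    f"line ID {lid!r} is not canonical DGRP_XXX",
                ))
        dup = table.data.duplicated(subset=["line_id", "sex"], keep="first")
        for i in np.flatnonzero(dup.to_numpy()):
            report.append(Violation(
                "duplicate_row", f"{study_id}:row{int(i)}",
                "duplicated (line, sex) row",
            ))
    for d in reg.descriptors:
        if d.study_id not in reg.studies:
            report.append(Violation(
                "bad_reference", d.label, "descriptor references unknown study",
            ))
            continue
        table = reg.tables.get(d.study_id)
        if table is None or d.phenotype_id not in table.phenotype_ids:
            report.append(Violation(
                "missing_column", d.label,
                "descriptor references a column absent from the study table",
            ))
        if d.dtype == "quantitative" and not d.unit.strip():
            report.append(Violation(
                "missing_unit", d.label, "quantitative phenotype without a unit",
            ))
    return report


@dataclass(frozen=True)
class RegistrySummary:
    per_sex: dict[str, int]
    per_study: dict[str, int]
    per_category: dict[str, int]
    total: int


def summarize_registry(reg: PhenotypeRegistry) -> RegistrySummary:
    """Phenotype counts per sex, per study and per category (additive)."""
    per_sex = {s: 0 for s in SEX_CODES}
    per_study: dict[str, int] = {sid: 0 for sid in sorted(reg.studies)}
    per_category: dict[str, int] = {}
    for d in reg.descriptors:
        per_sex[d.sex] += 1
        per_study[d.study_id] = per_study.get(d.study_id, 0) + 1
        study = reg.studies.get(d.study_id)
        for cat in (study.categories if study else ()):
            per_category[cat] = per_category.get(cat, 0) + 1
    return RegistrySummary(
        per_sex=per_sex,
        per_study=per_study,
        per_category=dict(sorted(per_category.items())),
        total=len(reg.descriptors),
    )


def violations_frame(report: list[Violation]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"code": v.code, "location": v.location, "message": v.message} for v in report],
        columns=["code", "location", "message"],
    )
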
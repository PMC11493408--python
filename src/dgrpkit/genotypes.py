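"""Genotype panel and covariate containers with their TSV formats.

Lines in a reference panel are near-fully homozygous, so a biallelic call is
coded 0 (ref/ref) or 1 (alt/alt); ``NaN`` marks a missing call.  Variants are
addressed as ``chrom:pos`` with 1-based positions on the standard chromosome
arms (2L, 2R, 3L, 3R, X, 4).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import TableFormatError

CHROMOSOMES = ("2L", "2R", "3L", "3R", "X", "4")
VARIANT_CLASSES = ("SNP", "deletion", "insertion", "MNP")

#: Published composition of the DGRP variant catalogue (dm3 assembly).
DGRP_VARIANT_CLASS_COUNTS = {
    "SNP": 3_963_420,
    "deletion": 293_363,
    "insertion": 169_053,
    "MNP": 12_591,
}
DGRP_TOTAL_VARIANTS = 4_438_427

COVARIATE_COLUMNS = ("symbiont", "sv1", "sv2", "sv3", "sv4", "sv5")

_VARIANT_COLUMNS = ["variant_id", "chrom", "pos", "ref", "alt", "vclass"]


@dataclass
class GenotypePanel:
    """Lines × biallelic variants over a homozygous panel.

    ``variants`` is a frame with columns variant_id, chrom, pos, ref, alt,
    vclass; ``calls`` is an (n_lines, n_variants) float array over {0, 1, NaN}.
    """

    lines: list[str]
    variants: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        missing_cols = set(_VARIANT_COLUMNS) - set(self.variants.columns)
        if missing_cols:
            raise TableFormatError(f"variant table lacks columns {sorted(missing_cols)}")
        if self.variants["variant_id"].duplicated().any():
            raise TableFormatError("duplicate variant IDs (chrom:pos must be unique)")
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.shape != (len(self.lines), len(self.variants)):
            raise TableFormatError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.lines)} lines x {len(self.variants)} variants"
            )
        vals = self.calls[~np.isnan(self.calls)]
        if vals.size and not np.isin(vals, (0.0, 1.0)).all():
            raise TableFormatError("calls must be 0, 1 or missing")

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.variants["variant_id"])

    def column(self, variant_id: str) -> np.ndarray:
        idx = self.variants.index[self.variants["variant_id"] == variant_id]
        if len(idx) == 0:
            raise TableFormatError(f"unknown variant {variant_id!r}")
        return self.calls[:, int(idx[0])]


def missing_fraction(panel: GenotypePanel) -> np.ndarray:
    """Per-variant fraction of missing calls."""
    return np.isnan(panel.calls).mean(axis=0)


def minor_allele_frequency(panel: GenotypePanel) -> np.ndarray:
    """Per-variant MAF on non-missing calls, folded to <= 0.5.

    Variants with no non-missing calls get NaN.
    """
    with np.errstate(invalid="ignore"):
        alt = np.nanmean(panel.calls, axis=0)
    return np.where(np.isnan(alt), np.nan, np.minimum(alt, 1.0 - alt))


@dataclass
class CovariateTable:
    """Per-line known covariates: symbiont infection status (0/1) plus five
    structural-variant genotypes treated as opaque categorical factors."""

    data: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        need = ("line_id",) + COVARIATE_COLUMNS
        missing = set(need) - set(self.data.columns)
        if missing:
            raise TableFormatError(f"covariate table lacks columns {sorted(missing)}")
        if self.data["line_id"].duplicated().any():
            raise TableFormatError("duplicate line in covariate table")
        if self.data[list(COVARIATE_COLUMNS)].isna().any().any():
            raise TableFormatError("missing covariate values are not allowed")

    @property
    def lines(self) -> list[str]:
        return list(self.data["line_id"])

    def aligned(self, lines: list[str]) -> pd.DataFrame:
        """Covariate rows reindexed to a line order; all lines must be present."""
        df = self.data.set_index("line_id")
        missing = [l for l in lines if l not in df.index]
        if missing:
            raise TableFormatError(f"covariates missing for lines {missing[:5]}")
        return df.loc[lines, list(COVARIATE_COLUMNS)]


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def write_genotype_panel(panel: GenotypePanel, geno_path: str | Path,
                         variants_path: str | Path) -> None:
    """Write the calls matrix (lines × variants, {0,1,NA}) and the variant
    metadata as two TSVs."""
    calls = pd.DataFrame(panel.calls, columns=panel.variant_ids)
    calls = calls.map(lambda v: "NA" if np.isnan(v) else str(int(v)))
    calls.insert(0, "line_id", panel.lines)
    calls.to_csv(geno_path, sep="\t", index=False)
    panel.variants[_VARIANT_COLUMNS].to_csv(variants_path, sep="\t", index=False)


def read_genotype_panel(geno_path: str | Path,
                        variants_path: str | Path) -> GenotypePanel:
    raw = pd.read_csv(geno_path, sep="\t", dtype=str, keep_default_na=False)
    if raw.columns[0] != "line_id":
        raise TableFormatError("genotype matrix must start with a line_id column")
    lines = list(raw["line_id"])
    calls = (
        raw.drop(columns="line_id")
        .replace({"NA": np.nan, "": np.nan})
        .astype(float)
        .to_numpy()
    )
    variants = pd.read_csv(variants_path, sep="\t", dtype={"pos": int})
    order = list(raw.columns[1:])
    if order != list(variants["variant_id"]):
        variants = variants.set_index("variant_id").loc[order].reset_index()
    return GenotypePanel(lines=lines, variants=variants, calls=calls)


def write_covariates(cov: CovariateTable, path: str | Path) -> None:
    cov.data.to_csv(path, sep="\t", index=False)


def read_covariates(path: str | Path) -> CovariateTable:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df["symbiont"] = df["symbiont"].astype(int)
    return CovariateTable(data=df)
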
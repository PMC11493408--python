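"""Fraction-of-extremeness scoring for panel lines.

Per phenotype, lines are ranked ascending with ties assigned the *minimum*
rank.  The 15% band cut-off ``c = ceil(0.15 * R_max)`` (rounded up to be
inclusive at either end) assigns -1 to ranks <= c, +1 to ranks >= R_max - c,
and 0 otherwise.  A line's fraction of extremeness (FoE) is the share of its
phenotypes assigned +-1; the adjusted per-phenotype value is rank / R_max,
reflected about 0.5 so that values below 0.15 mark either tail.

The upper band rule ``r >= R_max - c`` captures one more rank than the lower
band; this asymmetry is deliberate (the stated procedure is reproduced
verbatim) and surfaced in reports.  Because the band cut-off is rounded up
while the adjusted value is not, an assignment of +-1 can carry an adjusted
value above 0.15; such cases are counted as "violations".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptySelectionError, InsufficientDataError
from .panel import PhenotypeRegistry

EXTREME_BAND = 0.15
DEFAULT_MIN_PHENOS = 50
DEFAULT_CROSS_SEX_TOL = 0.05


def rank_min_ties(values) -> np.ndarray:
    """Ascending ranks with ties sharing the minimum rank of their group.

    Missing values stay NaN (unranked); requires at least two observed values.
    """
    v = np.asarray(values, dtype=float)
    mask = ~np.isnan(v)
    if mask.sum() < 2:
        raise InsufficientDataError("need >= 2 values to rank a phenotype")
    out = np.full(v.shape, np.nan)
    out[mask] = stats.rankdata(v[mask], method="min")
    return out


def extremeness_cutoff(r_max: int) -> int:
    """Inclusive 15% rank cut-off: ceil(0.15 * R_max); integers unchanged.

    e.g. a raw cut-off of 1.2 or 1.8 both round up to 2.
    """
    if r_max < 1:
        raise InsufficientDataError("R_max must be >= 1")
    return math.ceil(EXTREME_BAND * r_max)


def assign_extremeness(ranks, r_max: int, c: int) -> tuple[np.ndarray, bool]:
    """Per-line assignments in {-1, 0, +1} plus a degenerate-band flag.

    rank <= c -> -1; rank >= R_max - c -> +1; otherwise 0 (the -1 test is
    applied first when the bands overlap).  The flag is True when c >=
    R_max - c, i.e. every ranked line is extreme.
    """
    r = np.asarray(ranks, dtype=float)
    out = np.full(r.shape, np.nan)
    mask = ~np.isnan(r)
    a = np.zeros(int(mask.sum()))
    rm = r[mask]
    a[rm >= r_max - c] = 1.0
    a[rm <= c] = -1.0
    out[mask] = a
    degenerate = c >= r_max - c
    return out, degenerate


def fraction_of_extremeness(assignments, n_phenos: int | None = None) -> float:
    """Share of +-1 assignments among a line's phenotypes."""
    a = np.asarray(assignments, dtype=float)
    a = a[~np.isnan(a)]
    n = n_phenos if n_phenos is not None else a.size
    if n < 1:
        raise InsufficientDataError("fraction of extremeness undefined for 0 phenotypes")
    return float(np.sum(np.abs(a) == 1) / n)


def adjusted_extremeness(rank: float, r_max: int) -> float:
    """rank / R_max reflected about 0.5: v if v <= 0.5 else 1 - v.

    e.g. 0.91 -> 0.09; the maximum rank maps to 0.
    """
    if not (1 <= rank <= r_max):
        raise InsufficientDataError(f"rank {rank} outside [1, {r_max}]")
    v = rank / r_max
    return float(v if v <= 0.5 else 1.0 - v)


@dataclass
class ExtremenessRecord:
    """Extremeness of one (line, sex) over the selected phenotypes."""

    line: str
    sex: str
    assignments: dict[str, int]       # phenotype label -> -1/0/+1
    adjusted: dict[str, float]        # phenotype label -> adjusted value
    n_phenos: int
    foe: float


@dataclass
class ViolationReport:
    """Band-rounding bookkeeping: +-1 assignments whose (unrounded) adjusted
    value exceeds 0.15."""

    n_observations: int = 0           # all (line, phenotype) assignments
    n_extreme: int = 0                # +-1 assignments
    n_violations: int = 0
    degenerate_phenotypes: list[str] = field(default_factory=list)

    @property
    def rate(self) -> float:
        return self.n_violations / self.n_observations if self.n_observations else 0.0


@dataclass
class ExtremenessResult:
    records: list[ExtremenessRecord]            # lines meeting min_phenos
    all_records: list[ExtremenessRecord]        # before the min_phenos filter
    violations: ViolationReport
    phenotypes: list[str]                       # selected descriptor labels


def extremeness_pipeline(reg: PhenotypeRegistry, categories=None,
                         min_phenos: int = DEFAULT_MIN_PHENOS,
                         scope: str = "curated_only") -> ExtremenessResult:
    """Rank, band-assign and score every (line, sex) of a registry.

    ``categories`` filters studies by their category tags (case-insensitive;
    None or empty keeps all).  Lines with fewer than ``min_phenos`` scored
    phenotypes for a sex are excluded from the line-level records (they remain
    in ``all_records``); exclusion never changes other lines' FoE because
    ranks are per phenotype.
    """
    descs = reg.select_descriptors(scope=scope, dtype="quantitative",
                                   categories=categories or None)
    if not descs:
        raise EmptySelectionError("no phenotypes left after category/scope filtering")

    per_line: dict[tuple[str, str], dict[str, tuple[int, float]]] = {}
    violations = ViolationReport()
    labels = []
    for d in descs:
        series = reg.series(d).dropna()
        if len(series) < 2:
            continue
        labels.append(d.label)
        ranks = rank_min_ties(series.to_numpy())
        r_max = int(np.nanmax(ranks))
        c = extremeness_cutoff(r_max)
        assigned, degenerate = assign_extremeness(ranks, r_max, c)
        if degenerate:
            violations.degenerate_phenotypes.append(d.label)
        for line, r, a in zip(series.index, ranks, assigned):
            adj = adjusted_extremeness(r, r_max)
            violations.n_observations += 1
            if a != 0:
                violations.n_extreme += 1
                if adj > EXTREME_BAND:
                    violations.n_violations += 1
            per_line.setdefault((line, d.sex), {})[d.label] = (int(a), adj)

    all_records = []
    for (line, sex), vals in sorted(per_line.items()):
        assignments = {k: v[0] for k, v in vals.items()}
        adjusted = {k: v[1] for k, v in vals.items()}
        n = len(vals)
        all_records.append(ExtremenessRecord(
            line=line, sex=sex, assignments=assignments, adjusted=adjusted,
            n_phenos=n, foe=fraction_of_extremeness(list(assignments.values()), n),
        ))
    records = [r for r in all_records if r.n_phenos >= min_phenos]
    return ExtremenessResult(records=records, all_records=all_records,
                             violations=violations, phenotypes=labels)


@dataclass
class CrossSexPairing:
    """Most extreme and most moderate lines with sex-consistent FoE."""

    extreme: str | None
    moderate: str | None
    candidates: pd.DataFrame      # line, foe_F, foe_M, mean_foe, gap
    notice: str = ""


def cross_sex_pairings(records: list[ExtremenessRecord],
                       tol: float = DEFAULT_CROSS_SEX_TOL) -> CrossSexPairing:
    """Among lines measured in both sexes with |FoE_F - FoE_M| <= tol, pick
    the lines with the highest and lowest mean FoE across sexes."""
    foe = {}
    for r in records:
        foe.setdefault(r.line, {})[r.sex] = r.foe
    rows = []
    for line, d in sorted(foe.items()):
        if "F" in d and "M" in d:
            rows.append({
                "line": line, "foe_F": d["F"], "foe_M": d["M"],
                "mean_foe": (d["F"] + d["M"]) / 2,
                "gap": abs(d["F"] - d["M"]),
            })
    cols = ["line", "foe_F", "foe_M", "mean_foe", "gap"]
    table = pd.DataFrame(rows, columns=cols)
    if table.empty:
        return CrossSexPairing(extreme=None, moderate=None, candidates=table,
                               notice="no line has records for both sexes")
    ok = table[table["gap"] <= tol]
    if ok.empty:
        return CrossSexPairing(extreme=None, moderate=None, candidates=table,
                               notice=f"no line within cross-sex tolerance {tol}")
    return CrossSexPairing(
        extreme=str(ok.loc[ok["mean_foe"].idxmax(), "line"]),
        moderate=str(ok.loc[ok["mean_foe"].idxmin(), "line"]),
        candidates=table,
    )


def foe_frame(records: list[ExtremenessRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"line_id": r.line, "sex": r.sex, "n_phenos": r.n_phenos, "foe": r.foe}
         for r in records],
        columns=["line_id", "sex", "n_phenos", "foe"],
    )


def assignments_frame(records: list[ExtremenessRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        for label, a in r.assignments.items():
            rows.append({
                "line_id": r.line, "sex": r.sex, "phenotype": label,
                "assignment": a, "adjusted": r.adjusted[label],
            })
    return pd.DataFrame(rows, columns=["line_id", "sex", "phenotype",
                                       "assignment", "adjusted"])
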
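"""Sex-stratified phenotype-phenotype correlation with FDR control.

Phenotype pairs are compared by Spearman's rank correlation over the lines
both phenotypes measured, separately per sex and restricted to quantitative
phenotypes.  Pairs are tagged within-study vs cross-study; a focal-phenotype
query correlates one phenotype against all candidates, adjusts that family
with Benjamini-Hochberg, and clusters the significant hits into focal-like,
correlated and anti-correlated groups.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .errors import (
    DegeneratePhenotypeError,
    DgrpkitError,
    InsufficientDataError,
    LookupError_,
    OverlapError,
)
from .panel import PhenotypeDescriptor, PhenotypeRegistry

DEFAULT_MIN_OVERLAP = 10


@dataclass(frozen=True)
class CorrelationRecord:
    """Correlation of one same-sex phenotype pair over their shared lines."""

    a: PhenotypeDescriptor
    b: PhenotypeDescriptor
    rho: float
    p: float
    n_shared: int
    same_study: bool
    q: float | None = None

    def reversed(self) -> "CorrelationRecord":
        return replace(self, a=self.b, b=self.a)


def _paired(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DgrpkitError("x and y must be aligned by line")
    keep = ~(np.isnan(x) | np.isnan(y))
    return x[keep], y[keep]


def spearman(x, y, min_overlap: int = 3) -> tuple[float, float, int]:
    """Spearman rho, two-sided p and shared-line count for two aligned vectors.

    Pairs with either value missing are dropped first.  rho is the Pearson
    correlation of mid-ranks (average ranks for ties); p uses the t
    approximation.  Raises OverlapError below ``min_overlap`` shared lines and
    DegeneratePhenotypeError when either vector is constant after pairing.
    """
    xs, ys = _paired(x, y)
    n = len(xs)
    if n < max(3, min_overlap):
        raise OverlapError(f"only {n} shared observations (minimum {max(3, min_overlap)})")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise DegeneratePhenotypeError("zero variance after pairing; correlation undefined")
    rho, p = stats.spearmanr(xs, ys)
    return float(rho), float(p), n


def pearson(x, y, min_overlap: int = 3) -> tuple[float, float, int]:
    """Pearson correlation with the same pairing/guard semantics as spearman."""
    xs, ys = _paired(x, y)
    n = len(xs)
    if n < max(3, min_overlap):
        raise OverlapError(f"only {n} shared observations (minimum {max(3, min_overlap)})")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise DegeneratePhenotypeError("zero variance after pairing; correlation undefined")
    r, p = stats.pearsonr(xs, ys)
    return float(r), float(p), n


_METHODS = {"spearman": spearman, "pearson": pearson}


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q_i = min_{j >= rank(i)} (m * p_(j) / j), clipped at 1; order-preserving
    in p.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise DgrpkitError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class SkipReport:
    """Why candidate pairs were left out of a correlation run."""

    low_overlap: int = 0
    zero_variance: int = 0

    @property
    def total(self) -> int:
        return self.low_overlap + self.zero_variance


def correlate_registry(reg: PhenotypeRegistry, scope: str = "curated_only",
                       min_overlap: int = DEFAULT_MIN_OVERLAP,
                       ) -> tuple[list[CorrelationRecord], SkipReport]:
    """All unordered same-sex pairs of quantitative phenotypes in a registry.

    Records carry BH q-values computed over the full emitted family and are
    ordered deterministically by (study_id, phenotype_id, sex) of both ends.
    Pairs below the overlap minimum or with a constant ranked vector are
    skipped and counted, not emitted as NaN.
    """
    descs = reg.select_descriptors(scope=scope, dtype="quantitative")
    series = {d.key: reg.series(d) for d in descs}
    records: list[CorrelationRecord] = []
    skips = SkipReport()
    for i, a in enumerate(descs):
        for b in descs[i + 1:]:
            if a.sex != b.sex:
                continue
            sa, sb = series[a.key], series[b.key]
            shared = sa.index.intersection(sb.index)
            try:
                rho, p, n = spearman(
                    sa.loc[shared].to_numpy(), sb.loc[shared].to_numpy(),
                    min_overlap=min_overlap,
                )
            except OverlapError:
                skips.low_overlap += 1
                continue
            except DegeneratePhenotypeError:
                skips.zero_variance += 1
                continue
            records.append(CorrelationRecord(
                a=a, b=b, rho=rho, p=p, n_shared=n,
                same_study=(a.study_id == b.study_id),
            ))
    if records:
        q = bh_adjust([r.p for r in records])
        records = [replace(r, q=float(qi)) for r, qi in zip(records, q)]
    return records, skips


@dataclass(frozen=True)
class GroupSummary:
    count: int
    mean_abs_rho: float
    median_abs_rho: float


def within_cross_summary(records: list[CorrelationRecord]) -> dict[str, GroupSummary]:
    """Mean/median |rho| for within-study vs cross-study pairs.

    Empty groups are reported with count 0 and NaN summaries.
    """
    if not records:
        raise InsufficientDataError("no correlation records to summarize")
    out = {}
    for name, flag in (("within", True), ("cross", False)):
        vals = np.array([abs(r.rho) for r in records if r.same_study == flag])
        out[name] = GroupSummary(
            count=int(vals.size),
            mean_abs_rho=float(vals.mean()) if vals.size else float("nan"),
            median_abs_rho=float(np.median(vals)) if vals.size else float("nan"),
        )
    return out


@dataclass
class FocalAssociationResult:
    """Phenotypes significantly correlated with one focal phenotype."""

    focal: PhenotypeDescriptor
    method: str
    alpha: float
    records: list[CorrelationRecord]          # full candidate family, with q
    hits: list[CorrelationRecord]             # q <= alpha
    groups: dict[str, list[str]]              # group name -> descriptor labels
    skips: SkipReport


def _cluster_hits(reg, hits, method, min_overlap) -> dict[str, list[str]]:
    """Partition hits by average-linkage clustering of their mutual
    correlation matrix (distance 1 - rho), cut into three groups, labelled by
    each group's mean correlation with the focal phenotype."""
    labels = [h.b.label for h in hits]
    rho_to_focal = {h.b.label: h.rho for h in hits}
    if len(hits) < 3:
        groups = {"focal_like": [], "correlated": [], "anti_correlated": []}
        for h in hits:
            groups["correlated" if h.rho >= 0 else "anti_correlated"].append(h.b.label)
        return groups
    series = {h.b.label: reg.series(h.b) for h in hits}
    fn = _METHODS[method]
    k = len(hits)
    corr = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            sa, sb = series[labels[i]], series[labels[j]]
            shared = sa.index.intersection(sb.index)
            try:
                rho, _, _ = fn(sa.loc[shared].to_numpy(), sb.loc[shared].to_numpy(),
                               min_overlap=3)
            except (OverlapError, DegeneratePhenotypeError):
                rho = 0.0
            corr[i, j] = corr[j, i] = rho
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    link = average(squareform(dist, checks=False))
    assignment = fcluster(link, t=3, criterion="maxclust")
    cluster_ids = sorted(set(assignment))
    mean_rho = {
        cid: float(np.mean([rho_to_focal[l] for l, a in zip(labels, assignment) if a == cid]))
        for cid in cluster_ids
    }
    by_rho = sorted(cluster_ids, key=lambda cid: mean_rho[cid])
    names = {}
    names[by_rho[0]] = "anti_correlated"
    names[by_rho[-1]] = "focal_like"
    for cid in by_rho[1:-1]:
        names[cid] = "correlated"
    groups: dict[str, list[str]] = {"focal_like": [], "correlated": [], "anti_correlated": []}
    for label, cid in zip(labels, assignment):
        groups[names[cid]].append(label)
    return groups


def focal_associations(reg: PhenotypeRegistry, focal: PhenotypeDescriptor,
                       method: str = "spearman", alpha: float = 0.05,
                       min_overlap: int = DEFAULT_MIN_OVERLAP,
                       scope: str = "curated_only",
                       cross_sex: bool = False) -> FocalAssociationResult:
    """Correlate a focal phenotype against every other quantitative phenotype.

    The BH family is the focal candidate set (one family per query); hits are
    the candidates with q <= alpha, partitioned into focal-like, correlated
    and anti-correlated groups by hierarchical clustering.  By default
    candidates are restricted to the focal phenotype's sex; ``cross_sex=True``
    admits all sexes (values still join on shared lines).
    """
    if method not in _METHODS:
        raise DgrpkitError(f"unknown method {method!r}")
    if focal.key not in {d.key for d in reg.descriptors}:
        raise LookupError_(f"focal phenotype {focal.label} not in registry")
    if focal.dtype != "quantitative":
        raise DgrpkitError("focal phenotype must be quantitative")
    fn = _METHODS[method]
    candidates = [
        d for d in reg.select_descriptors(scope=scope, dtype="quantitative")
        if d.key != focal.key and (cross_sex or d.sex == focal.sex)
    ]
    sf = reg.series(focal)
    records: list[CorrelationRecord] = []
    skips = SkipReport()
    for d in candidates:
        sd = reg.series(d)
        shared = sf.index.intersection(sd.index)
        try:
            rho, p, n = fn(sf.loc[shared].to_numpy(), sd.loc[shared].to_numpy(),
                           min_overlap=min_overlap)
        except OverlapError:
            skips.low_overlap += 1
            continue
        except DegeneratePhenotypeError:
            skips.zero_variance += 1
            continue
        records.append(CorrelationRecord(
            a=focal, b=d, rho=rho, p=p, n_shared=n,
            same_study=(focal.study_id == d.study_id),
        ))
    if records:
        q = bh_adjust([r.p for r in records])
        records = [replace(r, q=float(qi)) for r, qi in zip(records, q)]
    hits = [r for r in records if r.q is not None and r.q <= alpha]
    groups = _cluster_hits(reg, hits, method, min_overlap)
    return FocalAssociationResult(
        focal=focal, method=method, alpha=alpha,
        records=records, hits=hits, groups=groups, skips=skips,
    )


def records_frame(records: list[CorrelationRecord]) -> pd.DataFrame:
    """Long-format frame of correlation records (one row per pair)."""
    return pd.DataFrame(
        [
            {
                "pheno_a": r.a.label, "pheno_b": r.b.label,
                "rho": r.rho, "p": r.p, "q": r.q,
                "n_shared": r.n_shared, "same_study": r.same_study,
            }
            for r in records
        ],
        columns=["pheno_a", "pheno_b", "rho", "p", "q", "n_shared", "same_study"],
    )


def correlation_heatmap(reg: PhenotypeRegistry, records, path) -> None:
    """Save a phenotype x phenotype rho heatmap (matplotlib, Agg backend)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = sorted({r.a.label for r in records} | {r.b.label for r in records})
    idx = {l: i for i, l in enumerate(labels)}
    mat = np.eye(len(labels))
    for r in records:
        i, j = idx[r.a.label], idx[r.b.label]
        mat[i, j] = mat[j, i] = r.rho
    fig, ax = plt.subplots(figsize=(max(4, len(labels) * 0.3),) * 2)
    im = ax.imshow(mat, vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(labels)), labels, rotation=90, fontsize=6)
    ax.set_yticks(range(len(labels)), labels, fontsize=6)
    fig.colorbar(im, ax=ax, label="Spearman rho")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
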
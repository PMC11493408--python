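"""Per-variant covariate-adjusted linear association and PheWAS lookup.

Mirrors the semantics of a PLINK2 ``--glm hide-covar`` run on a homozygous
panel: the phenotype is rank-inverse-normal transformed (Blom offset),
variants are filtered on per-variant missingness and minor-allele frequency,
and each retained variant is tested by ordinary least squares of the
transformed phenotype on [1, genotype, covariate indicators], reporting the
genotype term only.  Lines with a missing call are dropped per variant
(per-variant complete case).  Covariate screening (Kruskal-Wallis per factor,
one multifactor ANOVA, Shapiro-Wilk normality) is advisory: the association
model always includes all known covariates.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ConfigError,
    DegeneratePhenotypeError,
    InsufficientDataError,
    LookupError_,
    MonomorphicVariantError,
)
from .genotypes import (
    COVARIATE_COLUMNS,
    CovariateTable,
    GenotypePanel,
    minor_allele_frequency,
    missing_fraction,
)

#: Smallest p-value ever reported (log-scale plotting safety).
P_FLOOR = np.finfo(float).tiny

BLOM_OFFSET = 0.375


@dataclass(frozen=True)
class AssocConfig:
    """Filtering and reporting parameters of one association run."""

    geno_max_missing: float = 0.2
    maf_min: float = 0.01
    quantile_normalize: bool = True
    variance_standardize: bool = True
    report_thresholds: tuple[float, ...] = (1e-3, 1e-5, 1e-6)
    alpha_bonferroni: float = 0.05

    def __post_init__(self) -> None:
        if not (0 <= self.geno_max_missing < 1):
            raise ConfigError("geno_max_missing must be in [0, 1)")
        if not (0 < self.maf_min < 0.5):
            raise ConfigError("maf_min must be in (0, 0.5)")


@dataclass(frozen=True)
class AssocResult:
    """Genotype-term statistics for one variant / one phenotype."""

    variant_id: str
    beta: float
    se: float
    tstat: float
    p: float
    n_used: int
    maf: float


# ---------------------------------------------------------------------------
# transforms and filters
# ---------------------------------------------------------------------------

def rank_inverse_normal(y, offset: float = BLOM_OFFSET) -> np.ndarray:
    """Rank-based inverse normal transform, Phi^-1((r - c) / (n - 2c + 1)).

    Mid-ranks for ties, Blom offset c = 3/8 by default; missing values are
    preserved as NaN.  Raises on fewer than three observed values or a
    constant vector.
    """
    y = np.asarray(y, dtype=float)
    mask = ~np.isnan(y)
    n = int(mask.sum())
    if n < 3:
        raise InsufficientDataError(f"need >= 3 non-missing values, got {n}")
    obs = y[mask]
    if np.ptp(obs) == 0:
        raise DegeneratePhenotypeError("all phenotype values identical")
    r = stats.rankdata(obs, method="average")
    z = stats.norm.ppf((r - offset) / (n - 2 * offset + 1))
    out = np.full(y.shape, np.nan)
    out[mask] = z
    return out


@dataclass
class FilterReport:
    """Per-variant retention decision; reasons are mutually exclusive and
    missingness is checked before MAF."""

    retained: np.ndarray           # indices into the panel's variant axis
    reasons: pd.Series             # per variant: retained | missingness | maf

    @property
    def counts(self) -> dict[str, int]:
        return self.reasons.value_counts().to_dict()


def filter_variants(panel: GenotypePanel, cfg: AssocConfig) -> FilterReport:
    """Keep variants with missing-call fraction <= geno_max_missing and MAF
    (on non-missing calls, folded) >= maf_min."""
    miss = missing_fraction(panel)
    maf = minor_allele_frequency(panel)
    reasons = np.full(panel.n_variants, "retained", dtype=object)
    bad_miss = miss > cfg.geno_max_missing
    reasons[bad_miss] = "missingness"
    with np.errstate(invalid="ignore"):
        bad_maf = ~bad_miss & (np.isnan(maf) | (maf < cfg.maf_min))
    reasons[bad_maf] = "maf"
    retained = np.flatnonzero(reasons == "retained")
    return FilterReport(retained=retained,
                        reasons=pd.Series(reasons, index=panel.variant_ids))


# ---------------------------------------------------------------------------
# design matrix and OLS
# ---------------------------------------------------------------------------

def covariate_design(cov: pd.DataFrame, variance_standardize: bool = True) -> np.ndarray:
    """Columns for the six known covariates.

    Symbiont status enters as its 0/1 value (standardized when the flag is
    on); each structural-variant factor enters as indicator contrasts with
    the most frequent category as reference.
    """
    cols = []
    sym = cov["symbiont"].to_numpy(dtype=float)
    if variance_standardize and np.ptp(sym) > 0:
        sym = (sym - sym.mean()) / sym.std(ddof=0)
    cols.append(sym)
    for name in COVARIATE_COLUMNS[1:]:
        vals = cov[name].astype(str)
        ref = vals.value_counts().idxmax()
        for level in sorted(set(vals) - {ref}):
            cols.append((vals == level).to_numpy(dtype=float))
    if not cols:
        return np.empty((len(cov), 0))
    return np.column_stack(cols)


def _drop_collinear(X: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Indices of a maximal independent column subset (QR with pivoting)."""
    if X.shape[1] == 0:
        return np.array([], dtype=int)
    from scipy.linalg import qr

    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int((diag > tol * max(diag[0], 1.0)).sum()) if diag.size else 0
    return np.sort(piv[:rank])


def _ols_genotype_term(y: np.ndarray, g: np.ndarray, C: np.ndarray):
    """OLS of y on [1, g, C]; returns (beta_g, se_g, t, p, df)."""
    n = y.size
    X = np.column_stack([np.ones(n), g, C])
    keep = _drop_collinear(X)
    if 1 not in keep:
        raise MonomorphicVariantError("genotype collinear with intercept/covariates")
    if len(keep) < X.shape[1]:
        _warnings.warn("dropped collinear covariate column(s) from the design")
        X = X[:, keep]
    k = X.shape[1]
    df = n - k
    if df < 1:
        raise InsufficientDataError(f"no residual degrees of freedom (n={n}, k={k})")
    XtX = X.T @ X
    coef = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ coef
    sigma2 = float(resid @ resid) / df
    cov_beta = sigma2 * np.linalg.inv(XtX)
    gi = int(np.flatnonzero(keep == 1)[0])
    beta = float(coef[gi])
    se = float(np.sqrt(cov_beta[gi, gi]))
    if se == 0:
        t = np.inf if beta != 0 else 0.0
        p = P_FLOOR if beta != 0 else 1.0
    else:
        t = beta / se
        p = max(2.0 * stats.t.sf(abs(t), df), P_FLOOR)
    return beta, se, float(t), float(p), df


def fit_single_variant(y, g, cov: CovariateTable | None = None,
                       lines: list[str] | None = None,
                       variant_id: str = "?",
                       variance_standardize: bool = True) -> AssocResult:
    """Test one variant against an (already transformed) phenotype.

    ``y`` and ``g`` are aligned per line; lines missing either are dropped.
    With a covariate table, covariates enter the model as fixed effects and
    only the genotype term is reported (hide-covar semantics).
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    keep = ~(np.isnan(y) | np.isnan(g))
    yk, gk = y[keep], g[keep]
    n = yk.size
    if n == 0 or np.ptp(gk) == 0:
        raise MonomorphicVariantError(
            f"variant {variant_id} monomorphic among the {n} usable lines")
    if cov is not None:
        if lines is None:
            raise ConfigError("covariate-adjusted fits need the line order")
        used_lines = [l for l, k in zip(lines, keep) if k]
        C = covariate_design(cov.aligned(used_lines), variance_standardize)
    else:
        C = np.empty((n, 0))
    beta, se, t, p, _ = _ols_genotype_term(yk, gk, C)
    alt = float(gk.mean())
    return AssocResult(variant_id=variant_id, beta=beta, se=se, tstat=t, p=p,
                       n_used=n, maf=min(alt, 1 - alt))


# ---------------------------------------------------------------------------
# GWAS driver
# ---------------------------------------------------------------------------

@dataclass
class GwasResult:
    """Full association output for one phenotype."""

    phenotype: str
    results: pd.DataFrame          # sorted ascending by p
    filter_report: FilterReport
    skipped: dict[str, int]        # e.g. monomorphic-in-sample count
    n_lines_used: int

    def top_table(self, k: int = 1000) -> pd.DataFrame:
        return self.results.head(k)

    def hits(self, threshold: float = 1e-3) -> pd.DataFrame:
        return self.results[self.results["p"] < threshold]


def run_gwas(y: pd.Series, panel: GenotypePanel, cov: CovariateTable | None,
             cfg: AssocConfig = AssocConfig(), phenotype: str = "phenotype",
             ) -> GwasResult:
    """Filter variants, fit the per-variant model, and rank results by p.

    ``y`` is a raw per-line phenotype series indexed by canonical line ID;
    lines absent from the panel or missing the phenotype are dropped once,
    then each variant drops its own missing calls.  Deterministic: ties in p
    keep the panel's variant order.
    """
    y = y.reindex(panel.lines)
    mask = ~y.isna().to_numpy()
    lines = [l for l, m in zip(panel.lines, mask) if m]
    yv = y.to_numpy(dtype=float)[mask]
    if cfg.quantile_normalize:
        yv = rank_inverse_normal(yv)
    elif cfg.variance_standardize:
        if np.ptp(yv) == 0:
            raise DegeneratePhenotypeError("constant phenotype")
        yv = (yv - yv.mean()) / yv.std(ddof=0)
    report = filter_variants(panel, cfg)
    calls = panel.calls[mask][:, report.retained]
    if cov is not None:
        C = covariate_design(cov.aligned(lines), cfg.variance_standardize)
        keep_cols = _drop_collinear(C)
        if len(keep_cols) < C.shape[1]:
            _warnings.warn("dropped collinear covariate column(s) from the design")
            C = C[:, keep_cols]
    else:
        C = np.empty((len(lines), 0))
    k_cov = C.shape[1]
    if len(lines) < k_cov + 3:
        raise InsufficientDataError(
            f"only {len(lines)} usable lines for {k_cov} covariates")

    n = len(lines)
    ids = [panel.variant_ids[i] for i in report.retained]
    meta = panel.variants.iloc[report.retained]
    rows = np.empty((len(ids), 6))
    rows.fill(np.nan)
    skipped = {"monomorphic": 0}

    # fast path (Frisch-Waugh): variants with complete calls share one
    # covariate projection, so their genotype terms come from a single
    # residualization; variants with missing calls fall back to per-variant OLS.
    complete = ~np.isnan(calls).any(axis=0)
    X0 = np.column_stack([np.ones(n), C])
    Q, _ = np.linalg.qr(X0)
    df = n - X0.shape[1] - 1
    if complete.any() and df >= 1:
        G = calls[:, complete]
        y_res = yv - Q @ (Q.T @ yv)
        G_res = G - Q @ (Q.T @ G)
        gg = np.einsum("ij,ij->j", G_res, G_res)
        mono = np.ptp(G, axis=0) == 0
        gg_safe = np.where(gg > 1e-12, gg, np.nan)
        beta = (G_res.T @ y_res) / gg_safe
        rss = float(y_res @ y_res) - beta**2 * gg_safe
        sigma2 = np.maximum(rss, 0.0) / df
        with np.errstate(invalid="ignore", divide="ignore"):
            se = np.sqrt(sigma2 / gg_safe)
            t = beta / se
        p = np.maximum(2.0 * stats.t.sf(np.abs(t), df), P_FLOOR)
        exact = se == 0
        t[exact] = np.where(beta[exact] != 0, np.inf, 0.0)
        p[exact] = np.where(beta[exact] != 0, P_FLOOR, 1.0)
        alt = G.mean(axis=0)
        block = np.column_stack([beta, se, t, p, np.full(G.shape[1], n),
                                 np.minimum(alt, 1 - alt)])
        block[mono] = np.nan
        skipped["monomorphic"] += int(mono.sum())
        rows[complete] = block
    loop_idx = np.flatnonzero(~complete) if df >= 1 else np.arange(len(ids))
    for j in loop_idx:
        g = calls[:, j]
        keep = ~np.isnan(g)
        try:
            if keep.sum() == 0 or np.ptp(g[keep]) == 0:
                raise MonomorphicVariantError(ids[j])
            beta, se_j, t_j, p_j, _ = _ols_genotype_term(yv[keep], g[keep], C[keep])
        except (MonomorphicVariantError, InsufficientDataError):
            skipped["monomorphic"] += 1
            continue
        alt = float(g[keep].mean())
        rows[j] = (beta, se_j, t_j, p_j, int(keep.sum()), min(alt, 1 - alt))

    out = pd.DataFrame(rows, columns=["beta", "se", "tstat", "p", "n_used", "maf"])
    out.insert(0, "variant_id", ids)
    out.insert(1, "chrom", meta["chrom"].to_numpy())
    out.insert(2, "pos", meta["pos"].to_numpy())
    out = out[~out["p"].isna()].copy()
    out["n_used"] = out["n_used"].astype(int)
    out["_order"] = np.arange(len(out))
    out = out.sort_values(["p", "_order"], kind="stable").drop(columns="_order")
    out = out.reset_index(drop=True)
    return GwasResult(phenotype=phenotype, results=out, filter_report=report,
                      skipped=skipped, n_lines_used=n)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def bonferroni_threshold(alpha: float, n_variants: int) -> float:
    """Family-wise threshold alpha / m over the tested variants."""
    if n_variants < 1:
        raise ConfigError("need at least one tested variant")
    return alpha / n_variants


def significance_summary(results: pd.DataFrame,
                         cfg: AssocConfig = AssocConfig()) -> dict:
    """Hit counts at each reporting threshold plus the Bonferroni threshold
    (and its count) for the tested-variant family."""
    if results.empty:
        raise InsufficientDataError("no association results to summarize")
    p = results["p"].to_numpy()
    counts = {thr: int((p <= thr).sum()) for thr in cfg.report_thresholds}
    bonf = bonferroni_threshold(cfg.alpha_bonferroni, len(p))
    return {
        "n_tested": int(len(p)),
        "counts": counts,
        "bonferroni_threshold": bonf,
        "bonferroni_count": int((p <= bonf).sum()),
    }


def qq_data(results: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """(expected, observed) -log10 p pairs, most significant first."""
    if results.empty:
        raise InsufficientDataError("no association results")
    p = np.sort(results["p"].to_numpy())
    m = p.size
    expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)
    observed = -np.log10(p)
    return expected, observed


def genotype_group_values(y: pd.Series, g: np.ndarray,
                          lines: list[str]) -> dict[str, np.ndarray]:
    """Phenotype values split by call (ref-hom / alt-hom / missing)."""
    yv = y.reindex(lines).to_numpy(dtype=float)
    g = np.asarray(g, dtype=float)
    return {
        "ref": yv[g == 0],
        "alt": yv[g == 1],
        "missing": yv[np.isnan(g)],
    }


# ---------------------------------------------------------------------------
# covariate screening
# ---------------------------------------------------------------------------

@dataclass
class CovariateScreen:
    """Advisory tests between a raw phenotype and the six known covariates."""

    kruskal: dict[str, tuple[float, float]]   # factor -> (H statistic, p)
    anova: pd.DataFrame                       # multifactor ANOVA table
    shapiro: tuple[float, float]              # (W, p) on the raw phenotype
    notes: list[str] = field(default_factory=list)


def covariate_screen(y: pd.Series, cov: CovariateTable) -> CovariateScreen:
    """Kruskal-Wallis per factor (one at a time), one ANOVA over all six
    factors jointly, and a Shapiro-Wilk normality test of the phenotype.

    Informational only: the association model corrects for all covariates
    regardless of these results.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    aligned = cov.aligned([l for l in y.index if l in set(cov.lines)])
    yv = y.loc[aligned.index]
    keep = ~yv.isna()
    yv = yv[keep]
    aligned = aligned.loc[keep]
    if len(yv) < 3:
        raise InsufficientDataError("too few phenotype values for screening")

    notes: list[str] = []
    kruskal: dict[str, tuple[float, float]] = {}
    usable = []
    for name in COVARIATE_COLUMNS:
        groups = [yv[aligned[name] == lev].to_numpy()
                  for lev in pd.unique(aligned[name])]
        groups = [grp for grp in groups if grp.size > 0]
        if len(groups) < 2:
            notes.append(f"{name}: single category, skipped")
            continue
        stat, p = stats.kruskal(*groups)
        kruskal[name] = (float(stat), float(p))
        usable.append(name)

    df = aligned.copy()
    df["y"] = yv.to_numpy()
    if usable:
        formula = "y ~ " + " + ".join(f"C({n})" for n in usable)
        fit = smf.ols(formula, data=df).fit()
        anova = sm.stats.anova_lm(fit, typ=2)
    else:
        anova = pd.DataFrame()
        notes.append("no multi-category factors; ANOVA skipped")
    w, p_sw = stats.shapiro(yv.to_numpy())
    return CovariateScreen(kruskal=kruskal, anova=anova,
                           shapiro=(float(w), float(p_sw)), notes=notes)


# ---------------------------------------------------------------------------
# PheWAS
# ---------------------------------------------------------------------------

@dataclass
class PhewasResult:
    variant_id: str
    rows: pd.DataFrame    # phenotype, beta, se, tstat, p, n_used, maf
    notice: str = ""


class PhewasStore:
    """Per-phenotype association tables accumulated from prior GWAS runs."""

    def __init__(self) -> None:
        self._tables: dict[str, pd.DataFrame] = {}

    def add(self, phenotype: str, results: pd.DataFrame) -> None:
        self._tables[phenotype] = results

    def add_run(self, run: GwasResult) -> None:
        self.add(run.phenotype, run.results)

    @property
    def phenotypes(self) -> list[str]:
        return sorted(self._tables)

    def lookup(self, variant_id: str) -> PhewasResult:
        return phewas_lookup(variant_id, self)

    def table(self, phenotype: str) -> pd.DataFrame:
        if phenotype not in self._tables:
            raise LookupError_(f"no results stored for {phenotype!r}")
        return self._tables[phenotype]


def phewas_lookup(variant_id: str, store: PhewasStore) -> PhewasResult:
    """One variant's association row across every stored phenotype, sorted by
    ascending p.  Phenotypes where the variant was filtered out are absent;
    a variant present nowhere yields an empty result with a notice."""
    rows = []
    for pheno in store.phenotypes:
        tab = store.table(pheno)
        hit = tab[tab["variant_id"] == variant_id]
        if len(hit):
            row = hit.iloc[0][["beta", "se", "tstat", "p", "n_used", "maf"]].to_dict()
            row["phenotype"] = pheno
            rows.append(row)
    cols = ["phenotype", "beta", "se", "tstat", "p", "n_used", "maf"]
    if not rows:
        return PhewasResult(variant_id=variant_id,
                            rows=pd.DataFrame(columns=cols),
                            notice=f"variant {variant_id} passed filters in no phenotype")
    frame = pd.DataFrame(rows)[cols].sort_values("p", kind="stable").reset_index(drop=True)
    return PhewasResult(variant_id=variant_id, rows=frame)
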
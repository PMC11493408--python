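"""Seeded synthetic panels: lines, genotypes, covariates and multi-study
phenotypes with the statistical structure the analysis engines assume.

The phenotype generator is a two-level factor model.  Each study ``s`` has a
latent per-line factor ``f_s`` and all studies share one global factor ``g``;
phenotype ``j`` of study ``s`` is built as::

    x_j = sqrt(rho_x) * g + sqrt(rho_w - rho_x) * f_s + noise_sd * sqrt(1 - rho_w) * e_j

so that at ``noise_sd = 1`` the expected correlation between two phenotypes of
the same study is ``rho_w`` and between phenotypes of different studies is
``rho_x``.  Male and female copies combine a shared core with a sex-specific
draw of the same structure, ``y_sex = sqrt(a) * x + sqrt(1 - a) * z_sex``, so
the same-phenotype cross-sex correlation is ``a`` while within-sex structure
is preserved.  Spiked causal variants add ``beta * g_v`` and covariates add
``C @ gamma`` on top, on designated phenotypes.

All generators are fully deterministic under ``SimConfig.seed``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .genotypes import (
    CHROMOSOMES,
    COVARIATE_COLUMNS,
    DGRP_VARIANT_CLASS_COUNTS,
    CovariateTable,
    GenotypePanel,
    VARIANT_CLASSES,
    write_covariates,
    write_genotype_panel,
)
from .panel import (
    PhenotypeDescriptor,
    PhenotypeRegistry,
    PhenotypeTable,
    StudyMeta,
    write_registry,
)

_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class SpikedEffect:
    """One causal contribution: variant ``variant`` adds ``beta`` (in units of
    the phenotype noise scale) to phenotype ``phenotype`` of study ``study``."""

    variant: int
    beta: float
    study: int = 0
    phenotype: int = 0


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic panel.

    Correlation targets: ``within_corr`` (rho_w) between phenotypes of the same
    study, ``cross_corr`` (rho_x) across studies, ``cross_sex_corr`` between
    the M and F copies of one phenotype.  ``causal_effects`` spike genotype
    effects into designated phenotypes; ``covariate_effects`` (six gammas:
    symbiont + five structural variants) enter the phenotypes named in
    ``covariate_targets``.
    """

    n_lines: int = 200
    n_variants: int = 1000
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_studies: int = 2
    phenos_per_study: tuple[int, ...] = (5, 5)
    within_corr: float = 0.6
    cross_corr: float = 0.05
    cross_sex_corr: float = 0.5
    missing_rate: float = 0.0
    causal_effects: tuple[SpikedEffect, ...] = ()
    covariate_effects: tuple[float, ...] = (0.0,) * 6
    covariate_targets: tuple[tuple[int, int], ...] = ((0, 0),)
    noise_sd: float = 1.0
    symbiont_prevalence: float = 0.5
    sv_levels: int = 3
    sv_probs: tuple[float, ...] = (0.6, 0.3, 0.1)
    study_categories: tuple[str, ...] = ("Life history traits",)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigError(f"maf_range must satisfy 0 < low <= high <= 0.5, got {self.maf_range}")
        if not (0 <= self.missing_rate < 1):
            raise ConfigError("missing_rate must be in [0, 1)")
        if self.n_lines < 1 or self.n_variants < 1 or self.n_studies < 1:
            raise ConfigError("all counts must be >= 1")
        if len(self.phenos_per_study) != self.n_studies:
            raise ConfigError("phenos_per_study must have one entry per study")
        if any(k < 1 for k in self.phenos_per_study):
            raise ConfigError("all counts must be >= 1")
        if not (0 <= self.cross_corr <= self.within_corr <= 1):
            raise ConfigError("need 0 <= cross_corr <= within_corr <= 1")
        if not (0 <= self.cross_sex_corr <= 1):
            raise ConfigError("cross_sex_corr must be in [0, 1]")
        if len(self.covariate_effects) != len(COVARIATE_COLUMNS):
            raise ConfigError("covariate_effects must give six gammas")
        if len(self.sv_probs) != self.sv_levels or abs(sum(self.sv_probs) - 1) > 1e-9:
            raise ConfigError("sv_probs must be a distribution over sv_levels")
        for eff in self.causal_effects:
            if not (0 <= eff.variant < self.n_variants):
                raise ConfigError(f"causal variant index {eff.variant} out of range")
            if not (0 <= eff.study < self.n_studies):
                raise ConfigError(f"causal study index {eff.study} out of range")
            if not (0 <= eff.phenotype < self.phenos_per_study[eff.study]):
                raise ConfigError(f"causal phenotype index {eff.phenotype} out of range")


def _rng(cfg: SimConfig, stream: str) -> np.random.Generator:
    """Independent deterministic stream per generator (seed, stream-name)."""
    h = hashlib.sha256(f"{cfg.seed}:{stream}".encode()).digest()
    return np.random.default_rng(int.from_bytes(h[:8], "little"))


def line_ids(n_lines: int) -> list[str]:
    """Synthetic line identifiers DGRP_001..; panels beyond 999 lines (used
    only for sampling-calibration runs) get wider, non-guideline numbers."""
    return [f"DGRP_{i:03d}" for i in range(1, n_lines + 1)]


def simulate_genotypes(cfg: SimConfig) -> GenotypePanel:
    """Draw a biallelic homozygous-panel genotype matrix.

    Per-variant alt frequency is uniform in ``maf_range``; calls are
    independent Bernoulli draws per line; missingness is injected MCAR at
    ``missing_rate``.  Variant classes follow the published DGRP catalogue
    proportions.
    """
    if cfg.n_lines < 2:
        raise ConfigError("need at least 2 lines to simulate genotypes")
    rng = _rng(cfg, "genotypes")
    m = cfg.n_variants

    chrom = rng.choice(CHROMOSOMES, size=m)
    pos = np.zeros(m, dtype=int)
    seen: set[str] = set()
    for i in range(m):
        while True:
            p = int(rng.integers(1, 25_000_000))
            vid = f"{chrom[i]}:{p}"
            if vid not in seen:
                seen.add(vid)
                pos[i] = p
                break
    class_probs = np.array([DGRP_VARIANT_CLASS_COUNTS[c] for c in VARIANT_CLASSES], float)
    vclass = rng.choice(VARIANT_CLASSES, size=m, p=class_probs / class_probs.sum())
    ref = rng.choice(_BASES, size=m)
    alt = np.array([
        rng.choice([b for b in _BASES if b != r]) if c == "SNP" else {
            "deletion": "-", "insertion": f"{r}INS", "MNP": f"{r}{rng.choice(_BASES)}"
        }[c]
        for r, c in zip(ref, vclass)
    ])
    variants = pd.DataFrame({
        "variant_id": [f"{c}:{p}" for c, p in zip(chrom, pos)],
        "chrom": chrom, "pos": pos, "ref": ref, "alt": alt, "vclass": vclass,
    })

    freq = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=m)
    calls = (rng.random((cfg.n_lines, m)) < freq).astype(float)
    if cfg.missing_rate > 0:
        calls[rng.random(calls.shape) < cfg.missing_rate] = np.nan
    return GenotypePanel(lines=line_ids(cfg.n_lines), variants=variants, calls=calls)


def simulate_covariates(cfg: SimConfig) -> CovariateTable:
    """Draw the six known covariates: symbiont status ~ Bernoulli(prevalence),
    five categorical structural-variant factors with ``sv_probs``."""
    rng = _rng(cfg, "covariates")
    n = cfg.n_lines
    data = {"line_id": line_ids(n)}
    data["symbiont"] = (rng.random(n) < cfg.symbiont_prevalence).astype(int)
    levels = [f"c{k}" for k in range(cfg.sv_levels)]
    for name in COVARIATE_COLUMNS[1:]:
        data[name] = rng.choice(levels, size=n, p=np.asarray(cfg.sv_probs))
    return CovariateTable(data=pd.DataFrame(data))


def _structured_latents(rng, n_lines, phenos_per_study, rho_w, rho_x, noise_sd):
    """One draw of the factor model: list (per study) of (n_lines, k) arrays."""
    g = rng.standard_normal(n_lines)
    out = []
    for k in phenos_per_study:
        f = rng.standard_normal(n_lines)
        e = rng.standard_normal((n_lines, k))
        x = (
            np.sqrt(rho_x) * g[:, None]
            + np.sqrt(rho_w - rho_x) * f[:, None]
            + noise_sd * np.sqrt(1.0 - rho_w) * e
        )
        out.append(x)
    return out


def simulate_study_phenotypes(cfg: SimConfig, panel: GenotypePanel,
                              cov: CovariateTable) -> PhenotypeRegistry:
    """Generate a multi-study, sex-stratified phenotype registry.

    Studies are named S1..Sn with phenotypes p1..pk, all quantitative, both
    sexes measured for every line, and the correlation structure described in
    the module docstring.  Spiked causal and covariate effects are added to
    their designated phenotypes for both sexes; missingness is MCAR per cell.
    """
    if panel.n_lines != cfg.n_lines or len(cov.lines) != cfg.n_lines:
        raise ConfigError("panel/covariates do not match cfg.n_lines")
    rng = _rng(cfg, "phenotypes")
    a = cfg.cross_sex_corr
    core = _structured_latents(rng, cfg.n_lines, cfg.phenos_per_study,
                               cfg.within_corr, cfg.cross_corr, cfg.noise_sd)
    per_sex = {}
    for sex in ("F", "M"):
        z = _structured_latents(rng, cfg.n_lines, cfg.phenos_per_study,
                                cfg.within_corr, cfg.cross_corr, cfg.noise_sd)
        per_sex[sex] = [np.sqrt(a) * x + np.sqrt(1 - a) * zz
                        for x, zz in zip(core, z)]

    # fixed effects: spiked variants and covariates
    g_imputed = np.nan_to_num(panel.calls, nan=0.0)
    cov_num = cov.aligned(line_ids(cfg.n_lines)).copy()
    for c in COVARIATE_COLUMNS[1:]:
        cov_num[c] = pd.factorize(cov_num[c], sort=True)[0]
    cov_mat = cov_num.to_numpy(dtype=float)
    for sex in ("F", "M"):
        for eff in cfg.causal_effects:
            per_sex[sex][eff.study][:, eff.phenotype] += eff.beta * g_imputed[:, eff.variant]
        gamma = np.asarray(cfg.covariate_effects, dtype=float)
        if np.any(gamma != 0):
            shift = cov_mat @ gamma
            for s, j in cfg.covariate_targets:
                per_sex[sex][s][:, j] += shift

    reg = PhenotypeRegistry()
    lines = line_ids(cfg.n_lines)
    for s in range(cfg.n_studies):
        sid = f"S{s + 1}"
        k = cfg.phenos_per_study[s]
        pheno_ids = [f"p{j + 1}" for j in range(k)]
        rows = []
        for sex in ("F", "M"):
            vals = per_sex[sex][s].copy()
            if cfg.missing_rate > 0:
                vals[rng.random(vals.shape) < cfg.missing_rate] = np.nan
            block = pd.DataFrame(vals, columns=pheno_ids)
            block.insert(0, "sex", sex)
            block.insert(0, "line_id", lines)
            rows.append(block)
        table = PhenotypeTable(study_id=sid, data=pd.concat(rows, ignore_index=True))
        descriptors = [
            PhenotypeDescriptor(
                study_id=sid, phenotype_id=pid, name=f"{sid} trait {pid}",
                sex=sex, unit="a.u.", dtype="quantitative", is_summary=True,
            )
            for sex in ("F", "M") for pid in pheno_ids
        ]
        meta = StudyMeta(study_id=sid, title=f"Synthetic study {sid}",
                         categories=cfg.study_categories, status="curated")
        reg.add_study(meta, table, descriptors)
    return reg


def simulate_panel(cfg: SimConfig):
    """Convenience: genotypes, covariates and registry from one config."""
    panel = simulate_genotypes(cfg)
    cov = simulate_covariates(cfg)
    reg = simulate_study_phenotypes(cfg, panel, cov)
    return panel, cov, reg


def emit_fixtures(reg: PhenotypeRegistry, panel: GenotypePanel,
                  cov: CovariateTable, directory: str | Path) -> list[str]:
    """Write guideline-conformant TSV fixtures and return the file manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_registry(reg, directory)
    write_genotype_panel(panel, directory / "genotypes.tsv", directory / "variants.tsv")
    write_covariates(cov, directory / "covariates.tsv")
    manifest = sorted(p.name for p in directory.iterdir() if p.is_file())
    (directory / "MANIFEST.txt").write_text("\n".join(manifest) + "\n")
    return manifest


def config_from_dict(d: dict) -> SimConfig:
    """Build a SimConfig from a plain (YAML-loaded) mapping."""
    d = dict(d)
    if "causal_effects" in d:
        d["causal_effects"] = tuple(
            e if isinstance(e, SpikedEffect) else SpikedEffect(**e) if isinstance(e, dict)
            else SpikedEffect(*e)
            for e in d["causal_effects"]
        )
    for key in ("maf_range", "phenos_per_study", "covariate_effects",
                "sv_probs", "study_categories"):
        if key in d:
            d[key] = tuple(d[key])
    if "covariate_targets" in d:
        d["covariate_targets"] = tuple(tuple(t) for t in d["covariate_targets"])
    return SimConfig(**d)
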
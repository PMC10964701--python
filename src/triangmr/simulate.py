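"""Synthetic GWAS summary statistics under controlled causal scenarios.

Every downstream stage of the triangulation pipeline (instrument
selection, MR estimators, LD-score regression, colocalization) is
exercised on data generated here, with the generating truth disclosed so
tests can score recovery.  The generators emulate the statistical
structure of consortium case-control GWAS: tens of genome-wide-significant
instruments, log-odds scale effects with the standard
1/(2*maf*(1-maf)*n*cf*(1-cf)) variance approximation for binary traits,
block-autoregressive LD panels, and scenarios with and without a causal
effect, directional/balanced horizontal pleiotropy, confounding through a
latent trait, and shared or distinct causal variants within a region.

No individual-level genotypes are simulated: effects are drawn directly
on the summary-statistic scale, with LD entering through the panel
correlation matrix (marginal effects are LD-propagated true effects plus
independent sampling noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.stats import norm

from .coloc import RegionData
from .gwas_io import SummaryStatsTable
from .ldsc import LDScoreTable

__all__ = [
    "LDPanel", "MRScenario", "ColocScenario", "LdscScenario",
    "TraitAnnotationTable",
    "simulate_ld_panel", "simulate_mr_dataset", "simulate_coloc_region",
    "simulate_ldsc_dataset", "simulate_mr_arrays",
]

#: confounders screened for in the instrument filter
CONFOUNDER_TRAITS = [
    "body mass index", "waist circumference", "hip circumference",
    "waist-hip ratio", "percentage of body fat", "smoking",
    "alcohol consumption", "insomnia", "depression", "physical activity",
]


@dataclass
class LDPanel:
    """A variant grid with a block-diagonal AR(1) correlation matrix."""

    variants: pd.DataFrame  # variant_id, chrom, pos, maf, block
    corr: np.ndarray
    block_structure: list[tuple[int, float]]

    def __post_init__(self) -> None:
        n = len(self.variants)
        if self.corr.shape != (n, n):
            raise ValueError("correlation matrix shape mismatch")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_blocks(self) -> int:
        return int(self.variants["block"].max()) + 1

    def block_indices(self, b: int) -> np.ndarray:
        return np.flatnonzero(self.variants["block"].to_numpy() == b)


def simulate_ld_panel(n_variants: int, block_spec=((50, 0.9),),
                      maf_range=(0.05, 0.5), seed: int = 0,
                      pos_spacing: int = 50_000) -> LDPanel:
    """Block-diagonal AR(1) LD panel: within a block r(i,j) = rho^|i-j|.

    ``block_spec`` is a sequence of (block length, rho) cycled until
    ``n_variants`` are covered; cross-block correlation is zero, so the
    matrix is positive semi-definite by construction.
    """
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    for _, rho in block_spec:
        if not -1 < rho < 1:
            raise ValueError(f"autocorrelation {rho} outside (-1, 1)")
    rng = np.random.default_rng(seed)
    sizes, rhos = [], []
    i = 0
    while sum(sizes) < n_variants:
        size, rho = block_spec[i % len(block_spec)]
        sizes.append(min(size, n_variants - sum(sizes)))
        rhos.append(rho)
        i += 1

    corr = np.zeros((n_variants, n_variants))
    blocks = np.empty(n_variants, dtype=int)
    start = 0
    for b, (size, rho) in enumerate(zip(sizes, rhos)):
        idx = np.arange(size)
        corr[start:start + size, start:start + size] = \
            rho ** np.abs(idx[:, None] - idx[None, :])
        blocks[start:start + size] = b
        start += size

    maf = rng.uniform(*maf_range, size=n_variants)
    variants = pd.DataFrame({
        "variant_id": [f"rs{j + 1}" for j in range(n_variants)],
        "chrom": "1",
        "pos": (np.arange(n_variants) + 1) * pos_spacing,
        "maf": maf,
        "block": blocks,
    })
    return LDPanel(variants=variants, corr=corr,
                   block_structure=list(zip(sizes, rhos)))


@dataclass
class MRScenario:
    """Generating truth for one exposure/outcome summary-statistic pair."""

    m_instruments: int = 50
    beta_causal: float = 0.0
    exposure_effect_scale: float = 0.08
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    inside_violation: bool = False
    confounder_effect: float = 0.0
    n_exposure: int = 50_000
    n_outcome: int = 50_000
    outcome_type: str = "binary"
    case_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m_instruments < 2:
            raise ValueError("need at least 2 instruments")
        if self.n_exposure <= 0 or self.n_outcome <= 0:
            raise ValueError("sample sizes must be positive")
        if self.outcome_type == "binary" and not 0 < self.case_fraction < 1:
            raise ValueError("case_fraction must be in (0,1)")


@dataclass
class ColocScenario:
    q_snps: int = 200
    causal_config: str = "none"  # none|trait1_only|trait2_only|distinct|shared
    causal_effect_size: float = 8.0  # on the z-score scale
    n1: int = 50_000
    n2: int = 50_000
    ld_autocorrelation: float = 0.9
    seed: int = 0

    CONFIGS = ("none", "trait1_only", "trait2_only", "distinct", "shared")

    def __post_init__(self) -> None:
        if self.q_snps < 3:
            raise ValueError("q_snps must be >= 3")
        if self.causal_config not in self.CONFIGS:
            raise ValueError(f"causal_config must be one of {self.CONFIGS}")


@dataclass
class LdscScenario:
    m_snps: int = 20_000
    h2_trait1: float = 0.3
    h2_trait2: float = 0.3
    rg_true: float = 0.0
    n1: int = 50_000
    n2: int = 50_000
    n_overlap: int = 0
    pheno_corr: float | None = None  # default: rg * sqrt(h2_1 * h2_2)
    ld_score_distribution: dict = field(
        default_factory=lambda: {"shape": 2.0, "scale": 30.0})
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.h2_trait1 <= 1 or not 0 <= self.h2_trait2 <= 1:
            raise ValueError("heritabilities must lie in [0,1]")
        if abs(self.rg_true) > 1:
            raise ValueError("|rg_true| must be <= 1")


@dataclass
class TraitAnnotationTable:
    """Local stand-in for a phenome-scan lookup of instrument associations."""

    table: pd.DataFrame  # variant_id, trait_name, pvalue, proxy_r2

    def __post_init__(self) -> None:
        t = self.table
        if len(t) and (((t["pvalue"] <= 0) | (t["pvalue"] > 1)).any()
                       or ((t["proxy_r2"] < 0) | (t["proxy_r2"] > 1)).any()):
            raise ValueError("annotation pvalue/proxy_r2 out of range")


class SimulatedMRData(NamedTuple):
    exposure: SummaryStatsTable
    outcome: SummaryStatsTable
    annotations: TraitAnnotationTable
    truth: dict


def _se_per_allele(maf, n, case_fraction=None):
    var_g = 2.0 * maf * (1.0 - maf)
    if case_fraction is None:
        return 1.0 / np.sqrt(var_g * n)
    return 1.0 / np.sqrt(var_g * n * case_fraction * (1.0 - case_fraction))


def _two_sided_p(beta, se):
    p = 2.0 * norm.sf(np.abs(beta) / se)
    return np.clip(p, np.nextafter(0, 1), 1.0)


def simulate_mr_arrays(scenario: MRScenario, rng=None, maf=None) -> dict:
    """Fast path: instrument-level summary arrays without table overhead.

    Returns a dict with maf, gamma (true exposure effects), alpha (true
    direct/pleiotropic outcome effects), bx/sx and by/sy (observed
    summary betas and SEs), and confounded (bool mask of instruments
    acting through the latent confounder).
    """
    rng = np.random.default_rng(scenario.seed) if rng is None else rng
    m = scenario.m_instruments
    if maf is None:
        maf = rng.uniform(0.05, 0.5, size=m)
    sx = _se_per_allele(maf, scenario.n_exposure)
    cf = scenario.case_fraction if scenario.outcome_type == "binary" else None
    sy = _se_per_allele(maf, scenario.n_outcome, cf)

    # instrument relevance by construction: draw N(0, scale^2) truncated
    # away from zero so every instrument clears a minimal z on the exposure
    scale = scenario.exposure_effect_scale
    gamma = rng.normal(0.0, scale, size=m)
    floor = 6.0 * sx
    small = np.abs(gamma) < floor
    gamma[small] = np.sign(rng.standard_normal(small.sum())) * \
        (floor[small] + np.abs(rng.normal(0, scale / 2, size=small.sum())))

    if scenario.pleiotropy_sd > 0 or scenario.pleiotropy_mean != 0:
        if scenario.inside_violation and scenario.pleiotropy_sd > 0:
            gn = (gamma - gamma.mean()) / max(gamma.std(), 1e-12)
            eps = rng.standard_normal(m)
            alpha = scenario.pleiotropy_mean + scenario.pleiotropy_sd * (
                0.7 * gn + np.sqrt(1 - 0.49) * eps)
        else:
            alpha = rng.normal(scenario.pleiotropy_mean,
                               scenario.pleiotropy_sd, size=m)
        # directional pleiotropy is defined relative to the
        # exposure-increasing allele of each instrument
        alpha = np.sign(gamma) * alpha
    else:
        alpha = np.zeros(m)

    confounded = np.zeros(m, dtype=bool)
    if scenario.confounder_effect != 0.0:
        k = max(1, round(0.2 * m))
        confounded[rng.choice(m, size=k, replace=False)] = True
        # these variants act on a latent confounder that feeds both traits
        alpha = alpha + confounded * gamma * scenario.confounder_effect

    bx = rng.normal(gamma, sx)
    by = rng.normal(scenario.beta_causal * gamma + alpha, sy)
    return {"maf": maf, "gamma": gamma, "alpha": alpha,
            "bx": bx, "sx": sx, "by": by, "sy": sy, "confounded": confounded}


def simulate_mvmr_arrays(m_instruments: int = 50, theta=(0.2, -0.1),
                         effect_corr: float = 0.5,
                         effect_scale: float = 0.08,
                         n_exposure: int = 50_000, n_outcome: int = 50_000,
                         case_fraction: float | None = 0.2,
                         rng=None, seed: int = 0) -> dict:
    """Instrument-level summary arrays for two correlated exposures.

    Each instrument affects both exposures with correlated true effects
    (correlation ``effect_corr``); the outcome receives the conditional
    effects ``theta`` of the two exposures and sampling noise.  Returns
    bx (m, 2), sx (m, 2), by, sy and the generating truth.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    m = m_instruments
    maf = rng.uniform(0.05, 0.5, size=m)
    g1 = rng.normal(0.0, effect_scale, size=m)
    g2 = effect_corr * g1 + np.sqrt(1 - effect_corr ** 2) * \
        rng.normal(0.0, effect_scale, size=m)
    sx = _se_per_allele(maf, n_exposure)
    sy = _se_per_allele(maf, n_outcome, case_fraction)
    bx = np.column_stack([rng.normal(g1, sx), rng.normal(g2, sx)])
    by = rng.normal(theta[0] * g1 + theta[1] * g2, sy)
    return {"bx": bx, "sx": np.column_stack([sx, sx]), "by": by, "sy": sy,
            "maf": maf, "theta": np.asarray(theta, float),
            "g": np.column_stack([g1, g2])}


def simulate_mr_dataset(scenario: MRScenario,
                        panel: LDPanel | None = None) -> SimulatedMRData:
    """Exposure and outcome summary-statistic tables plus annotations.

    Instruments are placed in distinct LD blocks of ``panel`` (first
    variant of each block); the remaining panel variants receive
    LD-propagated marginal effects, so clumping has realistic shoulders
    to prune.  When ``panel`` is None an identity panel with one variant
    per instrument is generated from the scenario seed.
    """
    rng = np.random.default_rng(scenario.seed)
    m = scenario.m_instruments
    if panel is None:
        panel = simulate_ld_panel(m, block_spec=((1, 0.0),),
                                  seed=scenario.seed)
    if m > panel.n_blocks:
        raise ValueError(f"{m} instruments requested but the panel has only "
                         f"{panel.n_blocks} LD blocks")

    inst_idx = np.array([panel.block_indices(b)[0] for b in range(m)])
    maf_all = panel.variants["maf"].to_numpy(float)
    draws = simulate_mr_arrays(scenario, rng=rng, maf=maf_all[inst_idx])

    # LD-propagate true effects to the whole grid, then add sampling noise
    g_all = np.zeros(panel.n_variants)
    a_all = np.zeros(panel.n_variants)
    g_all[inst_idx] = draws["gamma"]
    a_all[inst_idx] = draws["alpha"]
    g_marg = panel.corr @ g_all
    a_marg = panel.corr @ a_all

    sx_all = _se_per_allele(maf_all, scenario.n_exposure)
    cf = scenario.case_fraction if scenario.outcome_type == "binary" else None
    sy_all = _se_per_allele(maf_all, scenario.n_outcome, cf)
    bx_all = rng.normal(g_marg, sx_all)
    by_all = rng.normal(scenario.beta_causal * g_marg + a_marg, sy_all)
    bx_all[inst_idx] = draws["bx"]
    by_all[inst_idx] = draws["by"]

    alleles_ea = rng.choice(["A", "C"], size=panel.n_variants)
    alleles_oa = np.where(alleles_ea == "A", "G", "T")  # never palindromic

    def table(beta, se, n, label, trait_type, cf=None):
        df = pd.DataFrame({
            "variant_id": panel.variants["variant_id"],
            "chrom": panel.variants["chrom"].astype(str),
            "pos": panel.variants["pos"].astype(int),
            "effect_allele": alleles_ea, "other_allele": alleles_oa,
            "eaf": maf_all, "beta": beta, "se": se,
            "pvalue": _two_sided_p(beta, se), "n": n,
        })
        if cf is not None:
            df["n_case"] = int(round(n * cf))
            df["n_control"] = n - int(round(n * cf))
            df["n"] = df["n_case"] + df["n_control"]
        return SummaryStatsTable(trait_label=label, trait_type=trait_type,
                                 data=df)

    exposure = table(bx_all, sx_all, scenario.n_exposure, "exposure",
                     "quantitative")
    outcome = table(by_all, sy_all, scenario.n_outcome, "outcome",
                    scenario.outcome_type,
                    cf if scenario.outcome_type == "binary" else None)

    conf_rows = []
    ids = panel.variants["variant_id"].to_numpy()
    for i, j in enumerate(np.flatnonzero(draws["confounded"])):
        conf_rows.append({
            "variant_id": ids[inst_idx[j]],
            "trait_name": CONFOUNDER_TRAITS[i % len(CONFOUNDER_TRAITS)],
            "pvalue": 1e-9, "proxy_r2": 0.95,
        })
    annotations = TraitAnnotationTable(pd.DataFrame(
        conf_rows, columns=["variant_id", "trait_name", "pvalue", "proxy_r2"]))

    truth = {
        "beta_causal": scenario.beta_causal,
        "pleiotropy_mean": scenario.pleiotropy_mean,
        "pleiotropy_sd": scenario.pleiotropy_sd,
        "confounder_effect": scenario.confounder_effect,
        "instrument_ids": list(ids[inst_idx]),
        "confounded_ids": list(ids[inst_idx[draws["confounded"]]]),
        "gamma": draws["gamma"].tolist(),
        "alpha": draws["alpha"].tolist(),
        "seed": scenario.seed,
    }
    return SimulatedMRData(exposure, outcome, annotations, truth)


def simulate_coloc_region(scenario: ColocScenario,
                          rng=None) -> tuple[RegionData, dict]:
    """One region's summary statistics for two traits plus the truth.

    Marginal z-scores are R @ lambda + chol(R) @ eps where lambda holds the
    configured causal non-centralities; for the ``distinct`` configuration
    the region is split into two zero-correlation halves so the two causal
    variants are in linkage equilibrium.
    """
    rng = np.random.default_rng(scenario.seed) if rng is None else rng
    q = scenario.q_snps
    rho = scenario.ld_autocorrelation
    if not -1 < rho < 1:
        raise ValueError("ld_autocorrelation outside (-1, 1)")
    half = q // 2
    if scenario.causal_config == "distinct":
        sizes = [half, q - half]
    else:
        sizes = [q]
    R = np.zeros((q, q))
    start = 0
    for size in sizes:
        idx = np.arange(size)
        R[start:start + size, start:start + size] = \
            rho ** np.abs(idx[:, None] - idx[None, :])
        start += size
    L = np.linalg.cholesky(R + 1e-10 * np.eye(q))

    lam1 = np.zeros(q)
    lam2 = np.zeros(q)
    c1 = c2 = None
    z_c = scenario.causal_effect_size
    if scenario.causal_config == "trait1_only":
        c1 = q // 4
        lam1[c1] = z_c
    elif scenario.causal_config == "trait2_only":
        c2 = q // 4
        lam2[c2] = z_c
    elif scenario.causal_config == "distinct":
        c1, c2 = half // 2, half + (q - half) // 2
        lam1[c1] = z_c
        lam2[c2] = z_c
    elif scenario.causal_config == "shared":
        c1 = c2 = q // 4
        lam1[c1] = z_c
        lam2[c2] = z_c

    z1 = R @ lam1 + L @ rng.standard_normal(q)
    z2 = R @ lam2 + L @ rng.standard_normal(q)
    se1 = np.full(q, 1.0 / np.sqrt(scenario.n1))
    se2 = np.full(q, 1.0 / np.sqrt(scenario.n2))
    table = pd.DataFrame({
        "variant_id": [f"rs{j + 1}" for j in range(q)],
        "beta1": z1 * se1, "se1": se1,
        "beta2": z2 * se2, "se2": se2,
    })
    center = q // 4 if c1 is None and c2 is None else (c1 if c1 is not None else c2)
    region = RegionData(region_id=f"sim_{scenario.causal_config}",
                        center_variant=f"rs{center + 1}", chrom="1",
                        start=0, end=q * 1000, table=table)
    truth = {"causal_config": scenario.causal_config,
             "causal_index_trait1": c1, "causal_index_trait2": c2}
    return region, truth


def simulate_ldsc_dataset(scenario: LdscScenario,
                          rng=None) -> tuple[LDScoreTable, pd.DataFrame]:
    """LD scores and per-SNP z-scores for two traits under polygenicity.

    Per SNP j the z pair is jointly normal with Var(z1) = 1 + n1*h2_1*l_j/M,
    Var(z2) analogous, and Cov = sqrt(n1*n2)*rg*sqrt(h2_1*h2_2)*l_j/M plus a
    sample-overlap intercept n_overlap*r_pheno/sqrt(n1*n2), with the
    phenotypic correlation taken as rg*sqrt(h2_1*h2_2).
    """
    rng = np.random.default_rng(scenario.seed) if rng is None else rng
    M = scenario.m_snps
    dist = scenario.ld_score_distribution
    ell = 1.0 + rng.gamma(dist["shape"], dist["scale"], size=M)

    h1, h2 = scenario.h2_trait1, scenario.h2_trait2
    n1, n2 = scenario.n1, scenario.n2
    v1 = 1.0 + n1 * h1 * ell / M
    v2 = 1.0 + n2 * h2 * ell / M
    r_pheno = (scenario.pheno_corr if scenario.pheno_corr is not None
               else scenario.rg_true * np.sqrt(h1 * h2))
    cov = (np.sqrt(n1 * n2) * scenario.rg_true * np.sqrt(h1 * h2) * ell / M
           + scenario.n_overlap * r_pheno / np.sqrt(n1 * n2))
    resid = v2 - cov ** 2 / v1
    bad = np.flatnonzero(resid < -1e-9)
    if bad.size:
        raise ValueError(f"implied z covariance not positive definite at "
                         f"SNP index {bad[0]}")
    resid = np.clip(resid, 0.0, None)
    a = rng.standard_normal(M)
    b = rng.standard_normal(M)
    z1 = np.sqrt(v1) * a
    z2 = cov / np.sqrt(v1) * a + np.sqrt(resid) * b

    snps = [f"rs{j + 1}" for j in range(M)]
    maf = rng.uniform(0.05, 0.5, size=M)
    scores = LDScoreTable(table=pd.DataFrame({"SNP": snps, "L2": ell,
                                              "MAF": maf}), M=M)
    ztab = pd.DataFrame({"SNP": snps, "Z1": z1, "Z2": z2,
                         "N1": n1, "N2": n2})
    return scores, ztab
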
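"""Bivariate LD-score regression: heritability, genetic covariance, rg.

Under a polygenic model the expected association chi-square of a variant
grows linearly in its LD score (the sum of squared correlations with all
panel variants):  E[z_j^2] = 1 + n*h2*l_j/M.  Regressing z^2 on LD scores
therefore estimates heritability while the free intercept absorbs
confounding inflation; regressing z1_j*z2_j on l_j estimates genetic
covariance while its free intercept absorbs sample overlap.  The genetic
correlation is rg = gcov / sqrt(h2_1 * h2_2).  Standard errors come from a
delete-a-block jackknife over contiguous variant blocks.

Pairs where either trait's heritability estimate is not positive are
reported as not available (``na_low_heritability``) rather than given a
meaningless rg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = ["LDScoreTable", "RgResult", "compute_ld_scores", "estimate_rg"]


@dataclass
class LDScoreTable:
    """Per-variant LD scores.  ``table`` columns: SNP, L2, MAF."""

    table: pd.DataFrame
    M: int

    def __post_init__(self) -> None:
        if (self.table["L2"] < 1 - 1e-9).any():
            raise ValueError("LD scores must be >= 1 (self r^2 included)")
        if self.M != len(self.table):
            raise ValueError("M must equal the number of score rows")


@dataclass
class RgResult:
    rg: float
    rg_se: float
    rg_p: float
    h2_1: float
    h2_1_se: float
    h2_2: float
    h2_2_se: float
    gcov_intercept: float
    status: str  # "ok" | "na_low_heritability"
    n_snps: int = 0

    @property
    def significant(self) -> bool:
        return self.status == "ok" and self.rg_p < 0.05


def compute_ld_scores(panel) -> LDScoreTable:
    """LD scores from a panel's correlation matrix: l_j = sum_k r(j,k)^2."""
    r2 = np.asarray(panel.corr) ** 2
    scores = r2.sum(axis=1)
    table = pd.DataFrame({
        "SNP": panel.variants["variant_id"].to_numpy(),
        "L2": scores,
        "MAF": panel.variants["maf"].to_numpy(float),
    })
    return LDScoreTable(table=table, M=len(table))


def _wls_sufficient(x, y, w, block_ids, n_blocks):
    """Weighted with-intercept regression via per-block sufficient statistics.

    Returns (intercept, slope, per-block stats) where stats is an
    (n_blocks, 5) array of [sum w, sum wx, sum wx^2, sum wy, sum wxy].
    """
    stats = np.zeros((n_blocks, 5))
    np.add.at(stats[:, 0], block_ids, w)
    np.add.at(stats[:, 1], block_ids, w * x)
    np.add.at(stats[:, 2], block_ids, w * x * x)
    np.add.at(stats[:, 3], block_ids, w * y)
    np.add.at(stats[:, 4], block_ids, w * x * y)
    inter, slope = _solve_from_stats(stats.sum(axis=0))
    return inter, slope, stats


def _solve_from_stats(s):
    sw, swx, swx2, swy, swxy = s
    det = sw * swx2 - swx ** 2
    slope = (sw * swxy - swx * swy) / det
    inter = (swy - slope * swx) / sw
    return inter, slope


def estimate_rg(z1: pd.DataFrame, z2: pd.DataFrame, scores: LDScoreTable,
                n1: int, n2: int, maf_min: float = 0.01,
                reference_snps=None, n_jackknife_blocks: int = 200,
                h2_floor: float = 0.0, use_h2_z_floor: bool = False,
                truncate: bool = False) -> RgResult:
    """Estimate genetic correlation between two traits from z-scores.

    ``z1``/``z2`` are DataFrames with columns SNP and Z; ``scores``
    supplies LD scores and MAFs.  Variants are intersected with
    ``reference_snps`` (when given) and filtered at ``maf >= maf_min``
    before regression, mirroring the merge-to-reference-list and MAF
    filters of standard LDSC practice.
    """
    if n_jackknife_blocks < 2:
        raise ValueError("need at least 2 jackknife blocks")
    merged = scores.table.merge(z1.rename(columns={"Z": "Z1"})[["SNP", "Z1"]],
                                on="SNP")
    merged = merged.merge(z2.rename(columns={"Z": "Z2"})[["SNP", "Z2"]],
                          on="SNP")
    if reference_snps is not None:
        merged = merged[merged["SNP"].isin(set(reference_snps))]
    merged = merged[merged["MAF"] >= maf_min].reset_index(drop=True)
    m = len(merged)
    if m < n_jackknife_blocks:
        raise ValueError(
            f"only {m} variants after filtering but {n_jackknife_blocks} "
            "jackknife blocks requested; reduce n_jackknife_blocks")

    ell = merged["L2"].to_numpy(float)
    zz1 = merged["Z1"].to_numpy(float)
    zz2 = merged["Z2"].to_numpy(float)
    M = scores.M
    block_ids = np.minimum((np.arange(m) * n_jackknife_blocks) // m,
                           n_jackknife_blocks - 1)
    B = n_jackknife_blocks

    y1, y2, yc = zz1 ** 2, zz2 ** 2, zz1 * zz2
    ones = np.ones(m)

    # step 1: unweighted pass to form heteroskedasticity weights
    i1, s1 = _solve_from_stats(_wls_sufficient(ell, y1, ones, block_ids, B)[2]
                               .sum(axis=0))
    i2, s2 = _solve_from_stats(_wls_sufficient(ell, y2, ones, block_ids, B)[2]
                               .sum(axis=0))
    ic, sc = _solve_from_stats(_wls_sufficient(ell, yc, ones, block_ids, B)[2]
                               .sum(axis=0))
    pred1 = np.maximum(i1 + s1 * ell, 0.1)
    pred2 = np.maximum(i2 + s2 * ell, 0.1)
    predc = ic + sc * ell
    w1 = 1.0 / pred1 ** 2
    w2 = 1.0 / pred2 ** 2
    wc = 1.0 / (pred1 * pred2 + predc ** 2)

    # step 2: weighted fits + jackknife sufficient statistics
    _, slope1, st1 = _wls_sufficient(ell, y1, w1, block_ids, B)
    _, slope2, st2 = _wls_sufficient(ell, y2, w2, block_ids, B)
    interc, slopec, stc = _wls_sufficient(ell, yc, wc, block_ids, B)

    h2_1 = slope1 * M / n1
    h2_2 = slope2 * M / n2
    gcov = slopec * M / np.sqrt(n1 * n2)

    # delete-a-block estimates for every quantity
    tot1, tot2, totc = st1.sum(axis=0), st2.sum(axis=0), stc.sum(axis=0)
    h2_1_b = np.empty(B)
    h2_2_b = np.empty(B)
    rg_b = np.full(B, np.nan)
    for b in range(B):
        _, sl1 = _solve_from_stats(tot1 - st1[b])
        _, sl2 = _solve_from_stats(tot2 - st2[b])
        _, slc = _solve_from_stats(totc - stc[b])
        h2_1_b[b] = sl1 * M / n1
        h2_2_b[b] = sl2 * M / n2
        prod = h2_1_b[b] * h2_2_b[b]
        if prod > 0:
            rg_b[b] = (slc * M / np.sqrt(n1 * n2)) / np.sqrt(prod)

    def _jk_se(theta_b):
        theta_b = theta_b[np.isfinite(theta_b)]
        nb = len(theta_b)
        if nb < 2:
            return np.nan
        return float(np.sqrt((nb - 1) / nb
                             * np.sum((theta_b - theta_b.mean()) ** 2)))

    h2_1_se = _jk_se(h2_1_b)
    h2_2_se = _jk_se(h2_2_b)

    low1 = h2_1 <= h2_floor or (use_h2_z_floor and h2_1 / h2_1_se < 1)
    low2 = h2_2 <= h2_floor or (use_h2_z_floor and h2_2 / h2_2_se < 1)
    if low1 or low2:
        return RgResult(rg=np.nan, rg_se=np.nan, rg_p=np.nan,
                        h2_1=h2_1, h2_1_se=h2_1_se,
                        h2_2=h2_2, h2_2_se=h2_2_se,
                        gcov_intercept=interc,
                        status="na_low_heritability", n_snps=m)

    rg = gcov / np.sqrt(h2_1 * h2_2)
    rg_se = _jk_se(rg_b)
    if abs(rg) > 1.25:
        warnings.warn(f"rg = {rg:.3f} outside [-1.25, 1.25]; the estimator "
                      "can overshoot when heritability is poorly estimated")
    if truncate:
        rg = float(np.clip(rg, -1.0, 1.0))
    rg_p = float(2 * norm.sf(abs(rg) / rg_se)) if rg_se > 0 else (
        0.0 if rg != 0 else 1.0)
    rg_p = min(max(rg_p, np.nextafter(0, 1)), 1.0)
    return RgResult(rg=float(rg), rg_se=rg_se, rg_p=rg_p,
                    h2_1=float(h2_1), h2_1_se=h2_1_se,
                    h2_2=float(h2_2), h2_2_se=h2_2_se,
                    gcov_intercept=float(interc), status="ok", n_snps=m)
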
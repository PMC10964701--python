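"""Two-sample Mendelian randomization estimators and sensitivity suite.

All estimators consume harmonized exposure/outcome effects (the frame
produced by :func:`triangmr.gwas_io.harmonize_pair`, or any mapping with
``exposure_beta``, ``exposure_se``, ``outcome_beta``, ``outcome_se``).
The multiplicative random-effects IVW estimator is the primary analysis;
MR-Egger, the (penalized) weighted median, MR-PRESSO, and MR-RAPS probe
robustness to horizontal pleiotropy, and the Steiger test checks that the
instruments explain more variance in the exposure than in the outcome
(causal direction).  Multivariable MR regresses outcome effects jointly on
several exposures' effects to obtain conditional estimates.

Ratio (Wald) standard errors are first-order delta approximations that
ignore exposure-side noise for IVW/WM/PWM/Egger; MR-RAPS is the estimator
in the suite that models exposure noise explicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import chi2, norm, t as t_dist

__all__ = [
    "MREstimate", "SteigerResult",
    "ratio_estimates", "ivw_estimate", "egger_estimate",
    "weighted_median_estimate", "presso", "raps_estimate",
    "steiger_test", "mvmr_fit", "mvmr_estimate",
]

Z95 = norm.ppf(0.975)
PWM_PENALTY_FACTOR = 20.0
HUBER_C = 1.345


@dataclass
class MREstimate:
    """One estimator's causal-effect result on the trait (log-odds) scale."""

    method: str
    beta: float
    se: float
    pvalue: float
    n_snps: int
    heterogeneity_q: float = np.nan
    heterogeneity_p: float = np.nan
    extras: dict = field(default_factory=dict)
    estimable: bool = True
    reason: str = ""

    @property
    def or_value(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci_low(self) -> float:
        return float(np.exp(self.beta - Z95 * self.se))

    @property
    def ci_high(self) -> float:
        return float(np.exp(self.beta + Z95 * self.se))

    @property
    def significant(self) -> bool:
        return self.estimable and self.pvalue < 0.05

    def to_dict(self) -> dict:
        d = {"method": self.method, "beta": self.beta, "se": self.se,
             "pvalue": self.pvalue, "or": self.or_value,
             "ci_low": self.ci_low, "ci_high": self.ci_high,
             "n_snps": self.n_snps, "q": self.heterogeneity_q,
             "q_p": self.heterogeneity_p}
        d.update(self.extras)
        return d


@dataclass
class SteigerResult:
    r2_exposure: float
    r2_outcome: float
    direction_correct: bool
    z_statistic: float
    pvalue: float
    indeterminate: bool = False


def _not_estimable(method: str, n: int, reason: str) -> MREstimate:
    return MREstimate(method=method, beta=np.nan, se=np.nan, pvalue=np.nan,
                      n_snps=n, estimable=False, reason=reason)


def _arrays(pairs):
    """Accept a harmonized DataFrame or a dict of arrays."""
    if isinstance(pairs, pd.DataFrame):
        get = lambda c: pairs[c].to_numpy(float) if c in pairs else None
    else:
        get = lambda c: (np.asarray(pairs[c], float)
                         if c in pairs and pairs[c] is not None else None)
    bx, sx = get("exposure_beta"), get("exposure_se")
    by, sy = get("outcome_beta"), get("outcome_se")
    if bx is None or by is None or sy is None:
        raise ValueError("pairs must provide exposure_beta, outcome_beta, "
                         "outcome_se (and ideally exposure_se)")
    if sx is None:
        sx = np.zeros_like(bx)
    return bx, sx, by, sy


def _pclip(p):
    return float(np.clip(p, np.nextafter(0, 1), 1.0))


def ratio_estimates(pairs):
    """Per-variant Wald ratios by/bx with first-order SEs sy/|bx|.

    Variants with a zero exposure beta are excluded with a warning.
    Returns (ratio, ratio_se) arrays.
    """
    bx, _, by, sy = _arrays(pairs)
    keep = bx != 0
    if not keep.all():
        warnings.warn(f"{(~keep).sum()} variant(s) with exposure beta = 0 "
                      "excluded from ratio estimates")
    bx, by, sy = bx[keep], by[keep], sy[keep]
    return by / bx, sy / np.abs(bx)


def _ivw_core(ratio, ratio_se):
    w = 1.0 / ratio_se ** 2
    beta = float(np.sum(w * ratio) / np.sum(w))
    q = float(np.sum(w * (ratio - beta) ** 2))
    m = len(ratio)
    se_fixed = 1.0 / np.sqrt(np.sum(w))
    scale = np.sqrt(max(1.0, q / (m - 1))) if m > 1 else 1.0
    return beta, float(se_fixed * scale), q, m


def ivw_estimate(pairs) -> MREstimate:
    """Multiplicative random-effects inverse-variance weighted estimate.

    The random-effects SE is the fixed-effect SE scaled by
    sqrt(max(1, Q/(m-1))), so it never drops below the fixed-effect SE.
    A single-variant input falls back to the Wald ratio.
    """
    ratio, ratio_se = ratio_estimates(pairs)
    m = len(ratio)
    if m == 0:
        return _not_estimable("IVW", 0, "no usable variants")
    if m == 1:
        beta, se = float(ratio[0]), float(ratio_se[0])
        return MREstimate(method="Wald", beta=beta, se=se,
                          pvalue=_pclip(2 * norm.sf(abs(beta) / se)),
                          n_snps=1)
    beta, se, q, _ = _ivw_core(ratio, ratio_se)
    return MREstimate(
        method="IVW", beta=beta, se=se,
        pvalue=_pclip(2 * norm.sf(abs(beta) / se)), n_snps=m,
        heterogeneity_q=q, heterogeneity_p=_pclip(chi2.sf(q, m - 1)),
        extras={"se_fixed": se / np.sqrt(max(1.0, q / (m - 1)))})


def egger_estimate(pairs) -> MREstimate:
    """MR-Egger: weighted regression with a free pleiotropy intercept.

    Pairs are oriented so every exposure beta is non-negative; the slope
    is the causal estimate and the intercept estimates the average
    directional pleiotropic effect.  SEs are inflated by
    sqrt(max(1, Q'/(m-2))) and p-values use a t reference with m-2 df.
    """
    bx, _, by, sy = _arrays(pairs)
    m = len(bx)
    if m < 3:
        return _not_estimable("Egger", m, "MR-Egger needs >= 3 variants")
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    x = bx * flip
    y = by * flip
    w = 1.0 / sy ** 2

    sw, swx = w.sum(), (w * x).sum()
    swx2, swy, swxy = (w * x * x).sum(), (w * y).sum(), (w * x * y).sum()
    det = sw * swx2 - swx ** 2
    slope = (sw * swxy - swx * swy) / det
    inter = (swy - slope * swx) / sw
    resid = y - inter - slope * x
    q = float(np.sum(w * resid ** 2))
    scale2 = max(1.0, q / (m - 2))
    se_slope = np.sqrt(sw / det * scale2)
    se_inter = np.sqrt(swx2 / det * scale2)
    p_slope = _pclip(2 * t_dist.sf(abs(slope) / se_slope, m - 2))
    p_inter = _pclip(2 * t_dist.sf(abs(inter) / se_inter, m - 2))
    return MREstimate(
        method="Egger", beta=float(slope), se=float(se_slope),
        pvalue=p_slope, n_snps=m, heterogeneity_q=q,
        heterogeneity_p=_pclip(chi2.sf(q, m - 2)),
        extras={"egger_intercept": float(inter),
                "egger_intercept_se": float(se_inter),
                "egger_intercept_p": p_inter})


def _weighted_median_rows(b, w):
    """Weighted 50th percentile with linear interpolation, row-wise.

    ``b`` and ``w`` are (B, m); returns length-B medians.  Cumulative
    weight positions are (cumsum(w) - w/2) / sum(w), the usual weighted
    median convention.
    """
    order = np.argsort(b, axis=1)
    bs = np.take_along_axis(b, order, axis=1)
    ws = np.take_along_axis(w, order, axis=1)
    tot = ws.sum(axis=1, keepdims=True)
    cums = (np.cumsum(ws, axis=1) - ws / 2.0) / tot
    out = np.empty(b.shape[0])
    for i in range(b.shape[0]):
        out[i] = np.interp(0.5, cums[i], bs[i])
    return out


def weighted_median(ratio, weight) -> float:
    """Weight-interpolated median of ratio estimates (1-D convenience)."""
    return float(_weighted_median_rows(np.asarray(ratio, float)[None, :],
                                       np.asarray(weight, float)[None, :])[0])


def weighted_median_estimate(pairs, penalized: bool = False,
                             n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """(Penalized) weighted median of the per-variant Wald ratios.

    Weights are inverse ratio variances.  When ``penalized``, each weight
    is multiplied by min(1, 20 * q_j) with q_j the upper-tail chi2_1
    probability of the variant's Cochran Q contribution, down-weighting
    heterogeneity outliers.  The SE comes from a seeded parametric
    bootstrap of the ratio estimates under the fitted common-effect model
    (resamples centered at the estimate with the per-variant ratio SEs),
    which keeps the test calibrated instead of double-counting the
    observed between-variant spread.
    """
    ratio, ratio_se = ratio_estimates(pairs)
    m = len(ratio)
    method = "PWM" if penalized else "WM"
    if m < 3:
        return _not_estimable(method, m, "weighted median needs >= 3 variants")
    w = 1.0 / ratio_se ** 2

    def pen_weights(r):
        bwm = weighted_median(r, w)
        qj = w * (r - bwm) ** 2
        pen = np.minimum(1.0, PWM_PENALTY_FACTOR * chi2.sf(qj, 1))
        return w * pen

    wt = pen_weights(ratio) if penalized else w
    if wt.sum() == 0:
        return _not_estimable(method, m, "all weights zero after penalization")
    beta = weighted_median(ratio, wt)

    rng = np.random.default_rng(seed)
    boot = beta + ratio_se[None, :] * rng.standard_normal((n_boot, m))
    boot_w = np.broadcast_to(wt, (n_boot, m))
    se = float(np.std(_weighted_median_rows(boot, boot_w), ddof=1))
    q = float(np.sum(w * (ratio - beta) ** 2))
    return MREstimate(
        method=method, beta=beta, se=se,
        pvalue=_pclip(2 * norm.sf(abs(beta) / se)), n_snps=m,
        heterogeneity_q=q, heterogeneity_p=_pclip(chi2.sf(q, m - 1)))


def _loo_slopes(bx, by, w):
    s1 = np.sum(w * bx * by)
    s2 = np.sum(w * bx * bx)
    return (s1 - w * bx * by) / (s2 - w * bx * bx)


def presso(pairs, n_sim: int = 1000, outlier_alpha: float = 0.05,
           seed: int = 0) -> MREstimate:
    """MR-PRESSO: simulation-based pleiotropy residual sum and outlier test.

    The observed RSS uses leave-one-out IVW slopes; the null distribution
    re-simulates both traits' betas from their sampling distributions
    under the leave-one-out fits.  If the global test p < 0.05 the
    headline estimate is IVW recomputed without the flagged outliers
    (with the raw estimate and a distortion p kept in ``extras``),
    mirroring the convention of reporting outlier-corrected results.
    """
    bx, sx, by, sy = _arrays(pairs)
    m = len(bx)
    if m < 4:
        return _not_estimable("PRESSO", m, "MR-PRESSO needs >= 4 variants")
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    if 1.0 / n_sim > outlier_alpha / m:
        warnings.warn(
            f"n_sim = {n_sim} cannot resolve the Bonferroni outlier level "
            f"{outlier_alpha}/{m}; smallest attainable p is {1.0 / n_sim:g}")
    rng = np.random.default_rng(seed)
    w = 1.0 / sy ** 2
    beta_loo = _loo_slopes(bx, by, w)
    res_obs = w * (by - beta_loo * bx) ** 2
    rss_obs = float(res_obs.sum())

    bx_sim = rng.normal(bx, sx, size=(n_sim, m))
    by_sim = rng.normal(beta_loo * bx, sy, size=(n_sim, m))
    s1 = np.sum(w * bx_sim * by_sim, axis=1, keepdims=True)
    s2 = np.sum(w * bx_sim ** 2, axis=1, keepdims=True)
    loo_sim = (s1 - w * bx_sim * by_sim) / (s2 - w * bx_sim ** 2)
    res_sim = w * (by_sim - loo_sim * bx_sim) ** 2
    rss_sim = res_sim.sum(axis=1)
    global_p = float(np.mean(rss_sim >= rss_obs))

    outlier_p = np.mean(res_sim >= res_obs[None, :], axis=0)
    outliers = np.flatnonzero(outlier_p * m < outlier_alpha)

    def _ivw_on(idx):
        return ivw_estimate({"exposure_beta": bx[idx], "exposure_se": sx[idx],
                             "outcome_beta": by[idx], "outcome_se": sy[idx]})

    raw = _ivw_on(np.arange(m))
    extras = {"global_p": global_p, "global_rss": rss_obs,
              "outliers": outliers.tolist(),
              "outlier_p": outlier_p.tolist(),
              "raw_beta": raw.beta, "raw_se": raw.se, "raw_p": raw.pvalue,
              "distortion_p": np.nan, "n_outliers": int(len(outliers))}
    if global_p < 0.05 and len(outliers) and len(outliers) < m - 1:
        keep = np.setdiff1d(np.arange(m), outliers)
        corrected = _ivw_on(keep)
        if corrected.beta != 0:
            d_obs = (raw.beta - corrected.beta) / abs(corrected.beta) * 100
            n_d = 500
            d_null = np.empty(n_d)
            for i in range(n_d):
                drop = rng.choice(m, size=len(outliers), replace=False)
                sub = _ivw_on(np.setdiff1d(np.arange(m), drop))
                d_null[i] = (raw.beta - sub.beta) / abs(sub.beta) * 100
            extras["distortion_p"] = float(np.mean(np.abs(d_null)
                                                   >= abs(d_obs)))
            extras["distortion_pct"] = float(d_obs)
        headline = corrected
    else:
        headline = raw
    return MREstimate(method="PRESSO", beta=headline.beta, se=headline.se,
                      pvalue=headline.pvalue, n_snps=headline.n_snps,
                      heterogeneity_q=headline.heterogeneity_q,
                      heterogeneity_p=headline.heterogeneity_p,
                      extras=extras)


def _raps_score(beta, tau2, bx, sx, by, sy, loss):
    d2 = sy ** 2 + beta ** 2 * sx ** 2 + tau2
    d = np.sqrt(d2)
    t = (by - beta * bx) / d
    if loss == "huber":
        psi = np.clip(t, -HUBER_C, HUBER_C)
    else:
        psi = t
    dt_db = -bx / d - t * beta * sx ** 2 / d2
    return float(np.sum(psi * dt_db)), t, psi, dt_db


def raps_estimate(pairs, overdispersion: bool = False,
                  loss: str = "simple") -> MREstimate:
    """MR-RAPS: profile-score estimation accounting for exposure noise.

    Solves sum_j psi(t_j(beta)) * dt_j/dbeta = 0 with
    t_j = (by_j - beta*bx_j)/sqrt(sy_j^2 + beta^2 sx_j^2 + tau^2); the
    overdispersion parameter tau^2 (systematic balanced pleiotropy) is
    profiled out via the second moment of the standardized residuals when
    enabled.  psi is the identity or a Huber score (c = 1.345).  The SE is
    the sandwich of the profile score; root finding is bracketed and
    deterministic.
    """
    if loss not in ("simple", "huber"):
        raise ValueError("loss must be 'simple' or 'huber'")
    bx, sx, by, sy = _arrays(pairs)
    m = len(bx)
    if m < 3:
        return _not_estimable("RAPS", m, "MR-RAPS needs >= 3 variants")

    def solve_beta(tau2):
        f = lambda b: _raps_score(b, tau2, bx, sx, by, sy, loss)[0]
        width = 1.0
        lo, hi = -width, width
        for _ in range(12):
            if np.sign(f(lo)) != np.sign(f(hi)):
                return brentq(f, lo, hi, xtol=1e-12)
            width *= 2.0
            lo, hi = -width, width
        return None

    # second-moment target of psi(T)*T under T ~ N(0,1)
    delta = 1.0 if loss == "simple" else 2 * norm.cdf(HUBER_C) - 1

    tau2 = 0.0
    if overdispersion:
        def moment_gap(t2):
            b = solve_beta(t2)
            if b is None:
                return np.nan
            _, t, psi, _ = _raps_score(b, t2, bx, sx, by, sy, loss)
            return float(np.sum(psi * t) - m * delta)

        if moment_gap(0.0) > 0:
            hi = float(np.mean(sy ** 2))
            for _ in range(40):
                if moment_gap(hi) < 0:
                    break
                hi *= 2.0
            else:
                return _not_estimable("RAPS", m,
                                      "overdispersion did not bracket")
            tau2 = brentq(moment_gap, 0.0, hi, xtol=1e-12)

    beta = solve_beta(tau2)
    if beta is None:
        return _not_estimable(
            "RAPS", m, "no sign change of the profile score in the bracket")
    score0, t, psi, dt_db = _raps_score(beta, tau2, bx, sx, by, sy, loss)
    h = 1e-6 * max(1.0, abs(beta))
    a = (_raps_score(beta + h, tau2, bx, sx, by, sy, loss)[0]
         - _raps_score(beta - h, tau2, bx, sx, by, sy, loss)[0]) / (2 * h)
    b_var = float(np.sum((psi * dt_db) ** 2))
    se = float(np.sqrt(b_var / a ** 2))
    z = abs(beta) / se if se > 0 else np.inf
    # t reference with m-1 df compensates the sandwich SE's small-sample
    # downward bias
    return MREstimate(
        method="RAPS", beta=float(beta), se=se,
        pvalue=_pclip(2 * t_dist.sf(z, m - 1)), n_snps=m,
        extras={"tau2": float(tau2), "loss": loss,
                "overdispersion": overdispersion})


def steiger_test(pairs, n_exposure: int, n_outcome: int) -> SteigerResult:
    """Directionality test: do the instruments explain more exposure variance?

    r2 per trait is sum_j 2*eaf_j*(1-eaf_j)*beta_j^2 (standardized-trait
    approximation, applied on the log-odds scale for binary traits); the z
    statistic compares Fisher-transformed multiple correlations.
    """
    if n_exposure < 4 or n_outcome < 4:
        raise ValueError("sample sizes must be >= 4")
    if isinstance(pairs, pd.DataFrame):
        eaf_x = pairs["exposure_eaf"].to_numpy(float)
        eaf_y = pairs["outcome_eaf"].to_numpy(float)
    else:
        eaf_x = np.asarray(pairs["exposure_eaf"], float)
        eaf_y = np.asarray(pairs["outcome_eaf"], float)
    bx, _, by, _ = _arrays(pairs)
    r2x = float(np.sum(2 * eaf_x * (1 - eaf_x) * bx ** 2))
    r2y = float(np.sum(2 * eaf_y * (1 - eaf_y) * by ** 2))
    for name, r2 in (("exposure", r2x), ("outcome", r2y)):
        if not 0 <= r2 < 1:
            raise ValueError(
                f"r2_{name} = {r2:.3g} outside [0,1); betas are probably "
                "not on a standardized scale")
    if r2x == r2y:
        return SteigerResult(r2x, r2y, direction_correct=False,
                             z_statistic=0.0, pvalue=1.0, indeterminate=True)
    z = (np.arctanh(np.sqrt(r2x)) - np.arctanh(np.sqrt(r2y))) / \
        np.sqrt(1.0 / (n_exposure - 3) + 1.0 / (n_outcome - 3))
    return SteigerResult(r2x, r2y, direction_correct=r2x > r2y,
                         z_statistic=float(z),
                         pvalue=_pclip(2 * norm.sf(abs(z))))


def mvmr_fit(bx_matrix, by, sy, exposure_names=None,
             sx_matrix=None) -> list[MREstimate]:
    """Weighted no-intercept regression of outcome betas on exposure betas.

    Returns one conditional estimate per exposure.  SEs carry the
    multiplicative overdispersion scale sqrt(max(1, Q/(m-k))).  When
    ``sx_matrix`` is given, a conditional instrument-strength F statistic
    per exposure (mean residual z^2 after projecting out the other
    exposures) is reported in ``extras``.
    """
    X = np.atleast_2d(np.asarray(bx_matrix, float))
    if X.shape[0] == 1:
        X = X.T  # a single exposure passed as a flat vector
    by = np.asarray(by, float)
    sy = np.asarray(sy, float)
    m, k = X.shape
    if m <= k:
        raise ValueError("need more instruments than exposures")
    names = exposure_names or [f"exposure_{i + 1}" for i in range(k)]
    w = 1.0 / sy ** 2
    xtwx = X.T @ (w[:, None] * X)
    cond = np.linalg.cond(xtwx)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError(f"exposure beta matrix is rank deficient; "
                         f"collinear exposures among {names}")
    xtwy = X.T @ (w * by)
    beta = np.linalg.solve(xtwx, xtwy)
    resid = by - X @ beta
    q = float(np.sum(w * resid ** 2))
    scale2 = max(1.0, q / (m - k))
    cov = np.linalg.inv(xtwx) * scale2
    ses = np.sqrt(np.diag(cov))

    cond_f = [np.nan] * k
    if sx_matrix is not None:
        SX = np.atleast_2d(np.asarray(sx_matrix, float))
        if SX.shape[0] == 1:
            SX = SX.T
        for i in range(k):
            others = np.delete(X, i, axis=1)
            wi = 1.0 / SX[:, i] ** 2
            if others.shape[1]:
                g = np.linalg.lstsq(np.sqrt(wi)[:, None] * others,
                                    np.sqrt(wi) * X[:, i], rcond=None)[0]
                r = X[:, i] - others @ g
            else:
                r = X[:, i]
            cond_f[i] = float(np.sum(wi * r ** 2) / (m - k))

    out = []
    for i in range(k):
        out.append(MREstimate(
            method="MVMR", beta=float(beta[i]), se=float(ses[i]),
            pvalue=_pclip(2 * norm.sf(abs(beta[i]) / ses[i])), n_snps=m,
            heterogeneity_q=q, heterogeneity_p=_pclip(chi2.sf(q, m - k)),
            extras={"exposure": names[i], "conditional_f": cond_f[i],
                    "cov": cov.tolist()}))
    return out


def mvmr_estimate(exposures, outcome, panel, p_threshold: float = 5e-8,
                  r2_threshold: float = 0.001, window_kb: int = 10_000,
                  palindromic_eaf_limit: float = 0.42) -> list[MREstimate]:
    """Multivariable MR from per-trait summary tables.

    Instruments are the union of each exposure's genome-wide-significant
    variants, jointly clumped on the supplied panel; outcome betas are
    regressed on the matrix of exposure betas without intercept.
    """
    from .gwas_io import harmonize_pair, kept
    from .instruments import select_instruments

    if len(exposures) < 1:
        raise ValueError("at least one exposure required")
    union_ids: list[str] = []
    for exp in exposures:
        sel = select_instruments(exp, panel, p_threshold=p_threshold,
                                 r2_threshold=r2_threshold,
                                 window_kb=window_kb)
        union_ids.extend(v for v in sel.variant_ids if v not in union_ids)
    if not union_ids:
        raise ValueError("no genome-wide-significant instruments in any "
                         "exposure")
    # joint clump of the union, ranked by the best p across exposures
    frames = []
    for exp in exposures:
        d = exp.data[exp.data["variant_id"].isin(union_ids)]
        frames.append(d[["variant_id", "chrom", "pos", "effect_allele",
                         "other_allele", "eaf", "beta", "se", "pvalue", "n"]])
    best = (pd.concat(frames).sort_values("pvalue")
            .drop_duplicates("variant_id"))
    from .gwas_io import SummaryStatsTable
    pooled = SummaryStatsTable("union", exposures[0].trait_type,
                               best.reset_index(drop=True))
    jointly = select_instruments(pooled, panel, p_threshold=1.0,
                                 r2_threshold=r2_threshold,
                                 window_kb=window_kb)
    ids = list(jointly.variant_ids)

    harm = [kept(harmonize_pair(exp, outcome, palindromic_eaf_limit))
            for exp in exposures]
    shared = set(ids)
    for h in harm:
        shared &= set(h["variant_id"])
    ids = [v for v in ids if v in shared]
    if len(ids) <= len(exposures):
        raise ValueError("fewer jointly usable instruments than exposures")

    X = np.column_stack([h.set_index("variant_id").loc[ids, "exposure_beta"]
                         .to_numpy(float) for h in harm])
    SX = np.column_stack([h.set_index("variant_id").loc[ids, "exposure_se"]
                          .to_numpy(float) for h in harm])
    h0 = harm[0].set_index("variant_id").loc[ids]
    by = h0["outcome_beta"].to_numpy(float)
    sy = h0["outcome_se"].to_numpy(float)
    names = [exp.trait_label for exp in exposures]
    return mvmr_fit(X, by, sy, exposure_names=names, sx_matrix=SX)
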
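"""Bayesian colocalization with per-variant approximate Bayes factors.

For a genomic region and two traits, five mutually exclusive hypotheses
are compared: no causal variant for either trait (H0), one causal variant
for trait 1 only (H1), for trait 2 only (H2), two distinct causal variants
(H3), and a single causal variant shared by both traits (H4).  Evidence is
accumulated from per-variant Wakefield approximate Bayes factors under the
"at most one causal variant per trait" assumption, and posterior
probabilities PPH0..PPH4 are returned.

Regions are +/- ``window_kb`` windows around each MR instrument; the
region-level PPH4 values are averaged across regions and the average is
compared with a calling threshold (default 0.75) to declare a shared
causal variant for the trait pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = [
    "RegionData", "ColocPosterior", "ColocSummary",
    "wakefield_log_abf", "coloc_region", "aggregate_coloc",
    "regions_from_instruments",
]

DEFAULT_P1 = 1e-4
DEFAULT_P2 = 1e-4
DEFAULT_P12 = 1e-5
DEFAULT_PRIOR_SD = 0.2
DEFAULT_WINDOW_KB = 500
DEFAULT_PPH4_THRESHOLD = 0.75


@dataclass
class RegionData:
    """Per-variant effects for both traits over one region.

    ``table`` columns: variant_id, beta1, se1, beta2, se2 (optionally
    maf, n1, n2).  All SEs must be positive.
    """

    region_id: str
    center_variant: str
    chrom: str
    start: int
    end: int
    table: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.table) and ((self.table["se1"] <= 0).any()
                                or (self.table["se2"] <= 0).any()):
            raise ValueError(f"region {self.region_id}: non-positive SE")

    @property
    def n_snps(self) -> int:
        return len(self.table)


@dataclass
class ColocPosterior:
    region_id: str
    pph0: float
    pph1: float
    pph2: float
    pph3: float
    pph4: float
    n_snps: int
    priors: tuple[float, float, float]
    prior_sds: tuple[float, float]

    def as_array(self) -> np.ndarray:
        return np.array([self.pph0, self.pph1, self.pph2, self.pph3, self.pph4])


@dataclass
class ColocSummary:
    regions: list[ColocPosterior]
    mean_pph4: float
    shared_call: bool
    threshold: float
    n_regions_dropped: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "region_id": r.region_id, "n_snps": r.n_snps,
            "PPH0": r.pph0, "PPH1": r.pph1, "PPH2": r.pph2,
            "PPH3": r.pph3, "PPH4": r.pph4,
        } for r in self.regions])


def wakefield_log_abf(beta, se, prior_sd):
    """Log approximate Bayes factor for association at one variant.

    log ABF = 0.5*log(V/(V+W)) + 0.5*z^2*W/(V+W) with V = se^2,
    W = prior_sd^2 and z = beta/se; monotone increasing in abs(z).
    """
    beta = np.asarray(beta, float)
    se = np.asarray(se, float)
    if np.any(se <= 0):
        raise ValueError("se must be positive")
    if np.any(np.asarray(prior_sd, float) <= 0):
        raise ValueError("prior_sd must be positive")
    v = se ** 2
    w = np.asarray(prior_sd, float) ** 2
    z2 = (beta / se) ** 2
    r = w / (v + w)
    return 0.5 * np.log1p(-r) + 0.5 * z2 * r


def _log_diff_exp(a: float, b: float) -> float:
    """log(exp(a) - exp(b)) for a >= b, -inf when the difference vanishes."""
    if b >= a:
        return -np.inf
    return a + np.log1p(-np.exp(b - a))


def coloc_region(region: RegionData,
                 p1: float = DEFAULT_P1, p2: float = DEFAULT_P2,
                 p12: float = DEFAULT_P12,
                 prior_sd_1: float = DEFAULT_PRIOR_SD,
                 prior_sd_2: float = DEFAULT_PRIOR_SD) -> ColocPosterior:
    """Posterior probabilities of H0..H4 for one region.

    All hypothesis evidence is accumulated in log space (log-sum-exp), so
    arbitrarily strong associations do not overflow.
    """
    if not (0 < p1 and 0 < p2 and 0 < p12):
        raise ValueError("priors must be positive")
    if p1 + p2 + p12 >= 0.1:
        raise ValueError("p1 + p2 + p12 >= 0.1: implausible per-SNP priors")
    t = region.table
    lbf1 = wakefield_log_abf(t["beta1"].to_numpy(), t["se1"].to_numpy(), prior_sd_1)
    lbf2 = wakefield_log_abf(t["beta2"].to_numpy(), t["se2"].to_numpy(), prior_sd_2)

    s1 = logsumexp(lbf1)
    s2 = logsumexp(lbf2)
    s12 = logsumexp(lbf1 + lbf2)
    lh = np.array([
        0.0,
        np.log(p1) + s1,
        np.log(p2) + s2,
        np.log(p1) + np.log(p2) + _log_diff_exp(s1 + s2, s12),
        np.log(p12) + s12,
    ])
    post = np.exp(lh - logsumexp(lh))
    post /= post.sum()
    return ColocPosterior(region.region_id, *post, n_snps=len(t),
                          priors=(p1, p2, p12),
                          prior_sds=(prior_sd_1, prior_sd_2))


def mean_pph4_call(pph4_values, threshold: float = DEFAULT_PPH4_THRESHOLD):
    """Unweighted mean of per-region PPH4 values and the shared-variant call.

    The pair-level call is ``mean > threshold`` (default 0.75).
    """
    mean = float(np.mean(np.asarray(list(pph4_values), float)))
    return mean, mean > threshold


def aggregate_coloc(regions: list[RegionData],
                    p1: float = DEFAULT_P1, p2: float = DEFAULT_P2,
                    p12: float = DEFAULT_P12,
                    prior_sd_1: float = DEFAULT_PRIOR_SD,
                    prior_sd_2: float = DEFAULT_PRIOR_SD,
                    threshold: float = DEFAULT_PPH4_THRESHOLD) -> ColocSummary:
    """Run every region and average PPH4 across regions.

    The shared-variant call is ``mean_pph4 > threshold``.  Regions with no
    shared variants are dropped with a warning and excluded from the mean.
    """
    if not regions:
        raise ValueError("no regions supplied")
    usable = [r for r in regions if r.n_snps >= 1]
    dropped = len(regions) - len(usable)
    if dropped:
        warnings.warn(f"{dropped} region(s) had no shared variants and were "
                      "excluded from the PPH4 average")
    if not usable:
        raise ValueError("all regions empty")
    posts = [coloc_region(r, p1, p2, p12, prior_sd_1, prior_sd_2)
             for r in usable]
    mean_pph4, call = mean_pph4_call([p.pph4 for p in posts], threshold)
    return ColocSummary(regions=posts, mean_pph4=mean_pph4,
                        shared_call=call, threshold=threshold,
                        n_regions_dropped=dropped)


def regions_from_instruments(instrument_ids, exposure, outcome,
                             window_kb: int = DEFAULT_WINDOW_KB) -> list[RegionData]:
    """Build one region per instrument: +/- window_kb around its position.

    ``exposure`` and ``outcome`` are SummaryStatsTable objects sharing a
    variant-id convention; each region's table contains the variants of
    both traits falling in the window, inner-joined on variant_id.
    Overlapping windows are deliberately not merged: each instrument
    defines its own region.
    """
    exp = exposure.data.set_index("variant_id")
    out = outcome.data.set_index("variant_id")
    regions = []
    for vid in instrument_ids:
        if vid not in exp.index:
            warnings.warn(f"instrument {vid} absent from exposure table; skipped")
            continue
        chrom = exp.loc[vid, "chrom"]
        pos = int(exp.loc[vid, "pos"])
        half = window_kb * 1000
        in_win = exp[(exp["chrom"] == chrom)
                     & (exp["pos"] >= pos - half) & (exp["pos"] <= pos + half)]
        shared = in_win.join(out, how="inner", rsuffix="_out")
        table = pd.DataFrame({
            "variant_id": shared.index,
            "beta1": shared["beta"].to_numpy(float),
            "se1": shared["se"].to_numpy(float),
            "beta2": shared["beta_out"].to_numpy(float),
            "se2": shared["se_out"].to_numpy(float),
        })
        regions.append(RegionData(
            region_id=f"{vid}_{window_kb}kb", center_variant=vid,
            chrom=str(chrom), start=pos - half, end=pos + half, table=table))
    return regions
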
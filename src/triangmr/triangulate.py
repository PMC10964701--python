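"""Evidence triangulation: map three analysis tracks to a causal verdict.

Genetic correlation (LDSC), Mendelian randomization, and colocalization
each end in a binary call (significant at p < 0.05 for LDSC/MR with a
direction; mean PPH4 > 0.75 for colocalization, which carries no
direction).  Crossing these calls yields ten possible result patterns
mapped onto nine explanations, where the "only MR significant" and
"LDSC/MR significant but opposite in direction" patterns share the
false-positive explanation.  A companion eight-domain risk-of-bias
assessment aggregates user-supplied domain judgments by a worst-domain
rule, with missing domains coerced to moderate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EvidenceProfile", "Verdict", "BiasAssessment",
           "classify_evidence", "overall_risk_of_bias",
           "profile_from_results", "EXPLANATION_TEXT", "BIAS_DOMAINS"]

LDSC_STATES = ("sig_pos", "sig_neg", "not_sig", "not_available")
MR_STATES = ("sig_pos", "sig_neg", "not_sig")
COLOC_STATES = ("shared", "not_shared")

EXPLANATION_TEXT = {
    "i": "strong genetic evidence for the causal association",
    "ii": "the genetic evidence remains controversial",
    "iii": "causal association without shared causal genetic variants",
    "iv": "possibly a false positive causal association",
    "v": "possibly a false negative causal association",
    "vi": "pleiotropy without shared causal genetic variants",
    "vii": "weak genetic evidence for the causal association",
    "viii": "not enough causality but with shared causal genetic variants",
    "ix": "no genetic evidence for the causal association",
}

BIAS_DOMAINS = (
    "weak_instrument", "pleiotropy", "sample_overlap",
    "population_stratification", "sensitivity_inconsistency",
    "lack_of_repeatability", "inconsistency_with_other_designs", "reporting",
)

_LEVELS = ("low", "moderate", "high")


@dataclass
class EvidenceProfile:
    """The three tracks' calls for one exposure-outcome pair."""

    pair_id: tuple[str, str]
    ldsc_state: str
    mr_state: str
    coloc_state: str
    mr_source: str = "primary_ivw"  # or "pleiotropy_adjusted"
    rg: float = np.nan
    rg_p: float = np.nan
    mr_or: float = np.nan
    mr_p: float = np.nan
    mean_pph4: float = np.nan

    def __post_init__(self) -> None:
        if self.ldsc_state not in LDSC_STATES:
            raise ValueError(f"ldsc_state must be one of {LDSC_STATES}")
        if self.mr_state not in MR_STATES:
            raise ValueError(f"mr_state must be one of {MR_STATES}")
        if self.coloc_state not in COLOC_STATES:
            raise ValueError(f"coloc_state must be one of {COLOC_STATES}")


@dataclass
class Verdict:
    pattern_index: int  # 1..10
    explanation_code: str  # i..ix
    explanation_text: str
    flags: list[str] = field(default_factory=list)


@dataclass
class BiasAssessment:
    domains: dict
    overall: str
    flags: list[str] = field(default_factory=list)


def classify_evidence(profile: EvidenceProfile) -> Verdict:
    """Deterministic, total mapping from track states to a verdict.

    Direction agreement compares sign(rg) with sign(log OR); the
    colocalization call carries no direction.  An LDSC result that is not
    available (too-low heritability) is treated as not significant and
    flagged ``ldsc_na_treated_as_ns``.
    """
    flags = []
    ldsc = profile.ldsc_state
    if ldsc == "not_available":
        ldsc = "not_sig"
        flags.append("ldsc_na_treated_as_ns")
    l_sig = ldsc in ("sig_pos", "sig_neg")
    m_sig = profile.mr_state in ("sig_pos", "sig_neg")
    shared = profile.coloc_state == "shared"
    same_dir = l_sig and m_sig and (ldsc == profile.mr_state)
    if profile.mr_source == "pleiotropy_adjusted":
        flags.append("mr_pleiotropy_adjusted")

    if l_sig and m_sig and shared:
        pattern, code = (1, "i") if same_dir else (2, "ii")
    elif l_sig and m_sig:
        pattern, code = (3, "iii") if same_dir else (4, "iv")
    elif not l_sig and m_sig and not shared:
        pattern, code = 5, "iv"
    elif l_sig and not m_sig and shared:
        pattern, code = 6, "v"
    elif l_sig and not m_sig:
        pattern, code = 7, "vi"
    elif m_sig and shared:
        pattern, code = 8, "vii"
    elif shared:
        pattern, code = 9, "viii"
    else:
        pattern, code = 10, "ix"
    return Verdict(pattern_index=pattern, explanation_code=code,
                   explanation_text=EXPLANATION_TEXT[code], flags=flags)


def profile_from_results(pair_id, rg_result, mr_estimate, coloc_summary,
                         mr_source: str = "primary_ivw",
                         alpha: float = 0.05) -> EvidenceProfile:
    """Build an EvidenceProfile from the three stage results."""
    if rg_result is None or rg_result.status != "ok":
        ldsc_state = "not_available"
        rg, rg_p = np.nan, np.nan
    else:
        rg, rg_p = rg_result.rg, rg_result.rg_p
        if rg_p < alpha:
            ldsc_state = "sig_pos" if rg > 0 else "sig_neg"
        else:
            ldsc_state = "not_sig"
    if mr_estimate.estimable and mr_estimate.pvalue < alpha:
        mr_state = "sig_pos" if mr_estimate.beta > 0 else "sig_neg"
    else:
        mr_state = "not_sig"
    coloc_state = "shared" if coloc_summary.shared_call else "not_shared"
    return EvidenceProfile(
        pair_id=pair_id, ldsc_state=ldsc_state, mr_state=mr_state,
        coloc_state=coloc_state, mr_source=mr_source,
        rg=rg, rg_p=rg_p, mr_or=mr_estimate.or_value,
        mr_p=mr_estimate.pvalue, mean_pph4=coloc_summary.mean_pph4)


def overall_risk_of_bias(domains: dict) -> BiasAssessment:
    """Worst-domain aggregation over the eight bias domains.

    Unknown domain names raise; missing domains are coerced to moderate
    (no information) and flagged.  Overall is high if any domain is high,
    else moderate if any is moderate, else low.
    """
    unknown = set(domains) - set(BIAS_DOMAINS)
    if unknown:
        raise ValueError(f"unknown domain(s) {sorted(unknown)}; valid "
                         f"domains are {list(BIAS_DOMAINS)}")
    flags = []
    filled = {}
    for d in BIAS_DOMAINS:
        v = domains.get(d)
        if v is None:
            filled[d] = "moderate"
            flags.append(f"{d}_missing_coerced_moderate")
            continue
        if v not in _LEVELS:
            raise ValueError(f"domain {d}: judgment must be one of {_LEVELS}")
        filled[d] = v
    if any(v == "high" for v in filled.values()):
        overall = "high"
    elif any(v == "moderate" for v in filled.values()):
        overall = "moderate"
    else:
        overall = "low"
    return BiasAssessment(domains=filled, overall=overall, flags=flags)
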
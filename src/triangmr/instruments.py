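"""Instrument selection, LD clumping, strength scoring, confounder filter.

Instruments are variants strongly associated with the exposure
(P < 5e-8 by default) and mutually independent after greedy LD clumping
(r^2 < 0.001 within a 10,000 kb window by default).  Per-variant strength
is summarized by R^2 = 2*EAF*(1-EAF)*beta^2 and F = beta^2/se^2, both
summed over the selected set; a mean or minimum F at or below 10 flags
weak-instrument risk but never auto-filters.  Instruments associated with
a configured list of confounder traits (at proxy R^2 >= 0.8 and
P <= 5e-8 by default, emulating a phenome-scan lookup) can be removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["InstrumentSet", "StrengthReport", "select_instruments",
           "instrument_strength", "remove_confounder_snps"]

DEFAULT_P_THRESHOLD = 5e-8
DEFAULT_R2_THRESHOLD = 0.001
DEFAULT_WINDOW_KB = 10_000
DEFAULT_PROXY_R2_MIN = 0.8
DEFAULT_P_MAX = 5e-8


@dataclass
class InstrumentSet:
    """Clumped genome-wide-significant variants with selection provenance."""

    variant_ids: list[str]
    pvalues: dict[str, float]
    provenance: dict = field(default_factory=dict)
    removal_log: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["variant_id", "trait_name", "pvalue", "proxy_r2"]))

    def __len__(self) -> int:
        return len(self.variant_ids)


@dataclass
class StrengthReport:
    per_variant: pd.DataFrame  # variant_id, r2_explained, f_statistic
    total_r2: float
    total_f: float
    min_f: float
    mean_f: float
    weak_instrument_flag: bool


def select_instruments(table, panel, p_threshold: float = DEFAULT_P_THRESHOLD,
                       r2_threshold: float = DEFAULT_R2_THRESHOLD,
                       window_kb: int = DEFAULT_WINDOW_KB) -> InstrumentSet:
    """Greedy LD clumping of significant variants.

    Candidates with p < ``p_threshold`` are ranked by ascending p-value
    (ties broken by variant id for determinism); the best remaining
    candidate is kept and all remaining candidates within ``window_kb``
    on the same chromosome with LD r^2 >= ``r2_threshold`` against it are
    discarded.  Variants absent from the panel are treated as independent
    of everything (kept) with a warning.
    """
    df = table.data
    cand = df[df["pvalue"] < p_threshold]
    if len(cand) == 0:
        warnings.warn("no variants pass the significance threshold; "
                      "returning an empty instrument set")
        return InstrumentSet([], {}, provenance={
            "p_threshold": p_threshold, "r2_threshold": r2_threshold,
            "window_kb": window_kb})
    cand = cand.sort_values(["pvalue", "variant_id"]).reset_index(drop=True)

    pid = panel.variants["variant_id"]
    pos_in_panel = pd.Series(np.arange(len(pid)), index=pid)
    corr = np.asarray(panel.corr)
    missing = [v for v in cand["variant_id"] if v not in pos_in_panel.index]
    if missing:
        warnings.warn(f"{len(missing)} candidate variant(s) missing from the "
                      "LD panel are treated as independent of everything")
    mset = set(missing)

    ids = cand["variant_id"].to_numpy()
    chroms = cand["chrom"].to_numpy()
    poss = cand["pos"].to_numpy()
    alive = np.ones(len(cand), dtype=bool)
    kept: list[int] = []
    for i in range(len(cand)):
        if not alive[i]:
            continue
        kept.append(i)
        alive[i] = False
        if ids[i] in mset:
            continue
        ki = pos_in_panel[ids[i]]
        for j in np.flatnonzero(alive):
            if chroms[j] != chroms[i]:
                continue
            if abs(int(poss[j]) - int(poss[i])) > window_kb * 1000:
                continue
            if ids[j] in mset:
                continue
            if corr[ki, pos_in_panel[ids[j]]] ** 2 >= r2_threshold:
                alive[j] = False
    sel = cand.iloc[kept]
    return InstrumentSet(
        variant_ids=list(sel["variant_id"]),
        pvalues=dict(zip(sel["variant_id"], sel["pvalue"])),
        provenance={"p_threshold": p_threshold, "r2_threshold": r2_threshold,
                    "window_kb": window_kb, "n_candidates": len(cand)})


def instrument_strength(instruments: InstrumentSet, table) -> StrengthReport:
    """Per-variant and summed R^2 and F statistics.

    R^2 = 2*EAF*(1-EAF)*beta^2 and F = beta^2/se^2, summed over the set as
    is conventional for reporting overall instrument strength.  The summed
    R^2 can exceed 1 when per-variant values are added on the log-odds
    scale; this is surfaced as a warning rather than an error.
    """
    df = table.data.set_index("variant_id")
    missing = [v for v in instruments.variant_ids if v not in df.index]
    if missing:
        raise ValueError(f"variants absent from the table: {missing}")
    sub = df.loc[instruments.variant_ids]
    if sub["eaf"].isna().any():
        bad = sub.index[sub["eaf"].isna()].tolist()
        raise ValueError(f"missing eaf for variant(s) {bad}")
    eaf = sub["eaf"].to_numpy(float)
    beta = sub["beta"].to_numpy(float)
    se = sub["se"].to_numpy(float)
    r2 = 2.0 * eaf * (1.0 - eaf) * beta ** 2
    f = beta ** 2 / se ** 2
    total_r2 = float(r2.sum())
    if total_r2 > 1:
        warnings.warn(f"summed R^2 = {total_r2:.3f} exceeds 1; per-variant "
                      "R^2 values on the log-odds scale over-add")
    per = pd.DataFrame({"variant_id": instruments.variant_ids,
                        "r2_explained": r2, "f_statistic": f})
    min_f = float(f.min()) if len(f) else np.nan
    mean_f = float(f.mean()) if len(f) else np.nan
    return StrengthReport(
        per_variant=per, total_r2=total_r2, total_f=float(f.sum()),
        min_f=min_f, mean_f=mean_f,
        weak_instrument_flag=bool(len(f) and (min_f <= 10 or mean_f <= 10)))


def _normalize(name: str) -> str:
    return " ".join(name.lower().split())


def remove_confounder_snps(instruments: InstrumentSet, annotations,
                           confounder_names,
                           proxy_r2_min: float = DEFAULT_PROXY_R2_MIN,
                           p_max: float = DEFAULT_P_MAX) -> InstrumentSet:
    """Drop instruments annotated to a confounder trait.

    An instrument is removed when an annotation row matches a confounder
    name (case-insensitive, whitespace-normalized) with proxy_r2 >=
    ``proxy_r2_min`` and pvalue <= ``p_max``.  Removals are logged on the
    returned set.
    """
    ann = annotations.table
    wanted = {_normalize(c) for c in confounder_names}
    if len(ann):
        unmatched = wanted - {_normalize(t) for t in ann["trait_name"]}
        if unmatched:
            warnings.warn("confounder name(s) not found in the annotation "
                          f"table: {sorted(unmatched)}")
    if len(ann) == 0:
        return InstrumentSet(list(instruments.variant_ids),
                             dict(instruments.pvalues),
                             provenance=dict(instruments.provenance))
    hits = ann[
        ann["trait_name"].map(_normalize).isin(wanted)
        & (ann["proxy_r2"] >= proxy_r2_min)
        & (ann["pvalue"] <= p_max)
        & ann["variant_id"].isin(instruments.variant_ids)
    ]
    removed = set(hits["variant_id"])
    keep = [v for v in instruments.variant_ids if v not in removed]
    prov = dict(instruments.provenance)
    prov.update({"confounder_filter": sorted(wanted),
                 "proxy_r2_min": proxy_r2_min, "p_max": p_max,
                 "n_removed": len(removed)})
    return InstrumentSet(
        variant_ids=keep,
        pvalues={v: p for v, p in instruments.pvalues.items() if v in keep},
        provenance=prov,
        removal_log=hits.reset_index(drop=True))
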
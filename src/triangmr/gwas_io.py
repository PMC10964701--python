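"""Reading, validating and harmonizing GWAS summary statistics.

Two-sample Mendelian randomization requires that exposure and outcome
effects refer to the same effect allele.  This module provides a validated
per-trait container (:class:`SummaryStatsTable`) and
:func:`harmonize_pair`, which aligns an outcome table to the exposure's
effect alleles, flipping signs and frequencies where the alleles are
swapped, resolving strand flips through base complements, and dropping
palindromic (A/T, C/G) variants whose strand cannot be inferred from the
allele frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SummaryStatsTable",
    "read_summary_stats",
    "write_summary_stats",
    "harmonize_pair",
    "write_harmonized",
    "FormatError",
    "EmptyInputError",
]

#: canonical column names of the TSV dialect
CANONICAL_COLUMNS = [
    "SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P",
    "N", "N_CASE", "N_CONTROL",
]

_CANON_TO_FIELD = {
    "SNP": "variant_id", "CHR": "chrom", "POS": "pos",
    "EA": "effect_allele", "OA": "other_allele", "EAF": "eaf",
    "BETA": "beta", "SE": "se", "P": "pvalue",
    "N": "n", "N_CASE": "n_case", "N_CONTROL": "n_control",
}

_MANDATORY = ["variant_id", "chrom", "pos", "effect_allele", "other_allele",
              "eaf", "beta", "se", "pvalue", "n"]

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class FormatError(ValueError):
    """A mandatory column is missing or unparseable."""


class EmptyInputError(ValueError):
    """No valid rows survived parsing/validation."""


def _complement(allele: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(allele)) if len(allele) > 1 \
        else COMPLEMENT[allele]


def is_palindromic(a1: str, a2: str) -> bool:
    """A/T and C/G pairs cannot be strand-resolved from alleles alone."""
    return {a1, a2} in ({"A", "T"}, {"C", "G"})


@dataclass
class SummaryStatsTable:
    """Per-variant association records for a single trait.

    ``data`` holds one row per variant with the canonical field names
    (``variant_id``, ``chrom``, ``pos``, ``effect_allele``, ``other_allele``,
    ``eaf``, ``beta``, ``se``, ``pvalue``, ``n`` and optionally
    ``n_case``/``n_control``).  Rows violating the invariants are removed
    at construction time and tallied in ``n_rejected``.
    """

    trait_label: str
    trait_type: str  # "quantitative" | "binary"
    data: pd.DataFrame
    n_rejected: int = 0
    rejection_log: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["variant_id", "reason"]))

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "binary"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def variant_ids(self) -> pd.Index:
        return pd.Index(self.data["variant_id"])


def _validate(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a raw frame into (valid rows, rejection log)."""
    reasons = pd.Series("", index=df.index, dtype=object)

    def flag(mask: pd.Series, reason: str) -> None:
        fresh = mask & (reasons == "")
        reasons[fresh] = reason

    num = {c: pd.to_numeric(df[c], errors="coerce")
           for c in ("pos", "eaf", "beta", "se", "pvalue", "n")}
    flag(num["se"].isna() | (num["se"] <= 0), "se not > 0")
    # eaf may be missing (NaN) -- handled downstream; out-of-range is rejected
    flag(num["eaf"].notna() & ((num["eaf"] <= 0) | (num["eaf"] >= 1)),
         "eaf outside (0,1)")
    flag(num["pvalue"].isna() | (num["pvalue"] <= 0) | (num["pvalue"] > 1),
         "pvalue outside (0,1]")
    flag(num["beta"].isna(), "beta unparseable")
    flag(num["n"].isna() | (num["n"] <= 0), "n not positive")

    ea = df["effect_allele"].astype(str).str.upper()
    oa = df["other_allele"].astype(str).str.upper()
    valid_seq = ea.str.fullmatch("[ACGT]+") & oa.str.fullmatch("[ACGT]+")
    flag(~valid_seq.fillna(False), "allele not an A/C/G/T sequence")
    flag(ea == oa, "effect_allele == other_allele")

    if "n_case" in df.columns and "n_control" in df.columns:
        ncase = pd.to_numeric(df["n_case"], errors="coerce")
        nctrl = pd.to_numeric(df["n_control"], errors="coerce")
        both = ncase.notna() & nctrl.notna()
        flag(both & (ncase + nctrl != num["n"]), "n_case + n_control != n")

    flag(df["variant_id"].duplicated(keep="first"), "duplicate variant_id")

    bad = reasons != ""
    log = pd.DataFrame({"variant_id": df.loc[bad, "variant_id"],
                        "reason": reasons[bad]})
    good = df.loc[~bad].copy()
    for c, s in num.items():
        good[c] = s[~bad]
    good["effect_allele"] = ea[~bad]
    good["other_allele"] = oa[~bad]
    good["pos"] = good["pos"].astype(int)
    good["chrom"] = good["chrom"].astype(str)
    return good.reset_index(drop=True), log.reset_index(drop=True)


def read_summary_stats(path, column_map: dict | None = None,
                       trait_type: str = "binary",
                       trait_label: str | None = None) -> SummaryStatsTable:
    """Read a (optionally gzipped) TSV of GWAS summary statistics.

    Parameters
    ----------
    column_map
        mapping from file headers to canonical headers (``SNP``, ``CHR``,
        ``POS``, ``EA``, ``OA``, ``EAF``, ``BETA``, ``SE``, ``P``, ``N``,
        optionally ``N_CASE``/``N_CONTROL``); identity when omitted.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if column_map:
        raw = raw.rename(columns=column_map)
    present = {c: _CANON_TO_FIELD[c] for c in raw.columns if c in _CANON_TO_FIELD}
    df = raw.rename(columns=present)
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        canon = [k for k, v in _CANON_TO_FIELD.items() if v in missing]
        raise FormatError(f"missing mandatory column(s): {', '.join(canon)}")
    good, log = _validate(df)
    if len(good) == 0:
        raise EmptyInputError(f"no valid rows in {path}")
    return SummaryStatsTable(
        trait_label=trait_label or str(path), trait_type=trait_type,
        data=good[[c for c in _CANON_TO_FIELD.values() if c in good.columns]],
        n_rejected=len(log), rejection_log=log)


def write_summary_stats(table: SummaryStatsTable, path) -> None:
    """Write a table back to the canonical TSV dialect."""
    inv = {v: k for k, v in _CANON_TO_FIELD.items()}
    table.data.rename(columns=inv).to_csv(path, sep="\t", index=False)


def _classify(row, limit: float):
    """Return (action, flip_sign) for one exposure/outcome allele pairing."""
    ea_x, oa_x = row.effect_allele_x, row.other_allele_x
    ea_y, oa_y = row.effect_allele_y, row.other_allele_y
    pal = is_palindromic(ea_x, oa_x)
    if pal:
        # alleles always "match" up to strand for palindromic pairs; use
        # frequency to infer orientation, or drop when too close to 0.5
        if {ea_y, oa_y} != {ea_x, oa_x}:
            return "dropped_mismatch", False
        eaf_x, eaf_y = row.eaf_x, row.eaf_y
        if np.isnan(eaf_x) or np.isnan(eaf_y):
            return "dropped_palindromic", False
        if min(eaf_x, 1 - eaf_x) > limit or min(eaf_y, 1 - eaf_y) > limit:
            return "dropped_palindromic", False
        # align symbols first, then let frequency decide the strand
        nominal_swap = ea_y != ea_x
        eaf_nominal = 1 - eaf_y if nominal_swap else eaf_y
        opposite = (eaf_x < 0.5) != (eaf_nominal < 0.5)
        flip = nominal_swap != opposite  # XOR: strand flip undoes symbol swap
        return ("flipped", True) if flip else ("kept_as_is", False)
    if (ea_y, oa_y) == (ea_x, oa_x):
        return "kept_as_is", False
    if (ea_y, oa_y) == (oa_x, ea_x):
        return "flipped", True
    try:
        cea, coa = _complement(ea_y), _complement(oa_y)
    except KeyError:
        return "dropped_mismatch", False
    if (cea, coa) == (ea_x, oa_x):
        return "kept_as_is", False
    if (cea, coa) == (oa_x, ea_x):
        return "flipped", True
    return "dropped_mismatch", False


def harmonize_pair(exposure: SummaryStatsTable, outcome: SummaryStatsTable,
                   palindromic_eaf_limit: float = 0.42) -> pd.DataFrame:
    """Align outcome effects to the exposure's effect alleles.

    Returns one row per variant shared by the two tables with columns
    ``variant_id``, ``exposure_beta/se/eaf``, ``outcome_beta/se/eaf``,
    ``exposure_pvalue``, ``outcome_pvalue``, ``palindromic`` and ``action``
    (one of ``kept_as_is``, ``flipped``, ``dropped_palindromic``,
    ``dropped_mismatch``).  For retained rows both betas refer to the
    exposure's effect allele.
    """
    merged = exposure.data.merge(outcome.data, on="variant_id",
                                 suffixes=("_x", "_y"))
    if len(merged) == 0:
        raise EmptyInputError(
            "no shared variant ids between exposure and outcome; "
            "check that both tables use the same variant-id convention")

    actions, flips = [], []
    for row in merged.itertuples():
        action, flip = _classify(row, palindromic_eaf_limit)
        actions.append(action)
        flips.append(flip)
    flips = np.asarray(flips)
    out_beta = merged["beta_y"].to_numpy(float).copy()
    out_eaf = merged["eaf_y"].to_numpy(float).copy()
    out_beta[flips] *= -1.0
    out_eaf[flips] = 1.0 - out_eaf[flips]

    return pd.DataFrame({
        "variant_id": merged["variant_id"],
        "chrom": merged["chrom_x"],
        "pos": merged["pos_x"],
        "effect_allele": merged["effect_allele_x"],
        "other_allele": merged["other_allele_x"],
        "exposure_beta": merged["beta_x"].to_numpy(float),
        "exposure_se": merged["se_x"].to_numpy(float),
        "exposure_eaf": merged["eaf_x"].to_numpy(float),
        "exposure_pvalue": merged["pvalue_x"].to_numpy(float),
        "outcome_beta": out_beta,
        "outcome_se": merged["se_y"].to_numpy(float),
        "outcome_eaf": out_eaf,
        "outcome_pvalue": merged["pvalue_y"].to_numpy(float),
        "palindromic": [is_palindromic(a, b) for a, b in
                        zip(merged["effect_allele_x"], merged["other_allele_x"])],
        "action": actions,
    })


def kept(harmonized: pd.DataFrame) -> pd.DataFrame:
    """Rows usable for MR (kept or flipped)."""
    return harmonized[harmonized["action"].isin(["kept_as_is", "flipped"])] \
        .reset_index(drop=True)


def write_harmonized(harmonized: pd.DataFrame, path) -> None:
    df = harmonized.rename(columns={"action": "ACTION"})
    df.to_csv(path, sep="\t", index=False)
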
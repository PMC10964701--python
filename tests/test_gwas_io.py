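"""Reading, validation and allele harmonization."""

import gzip

import numpy as np
import pandas as pd
import pytest

from triangmr.gwas_io import (EmptyInputError, FormatError, SummaryStatsTable,
                              harmonize_pair, kept, read_summary_stats,
                              write_summary_stats)

HEADER = "SNP\tCHR\tPOS\tEA\tOA\tEAF\tBETA\tSE\tP\tN\n"


def _write(tmp_path, lines, name="stats.tsv"):
    path = tmp_path / name
    path.write_text(HEADER + "".join(lines))
    return path


GOOD_LINES = [
    "rs1\t1\t1000\tA\tG\t0.30\t0.10\t0.02\t1e-9\t50000\n",
    "rs2\t1\t2000\tC\tT\t0.20\t-0.05\t0.01\t1e-8\t50000\n",
    "rs3\t2\t3000\tG\tA\t0.45\t0.02\t0.02\t0.04\t50000\n",
]


def test_well_formed_file_parses_fully(tmp_path):
    t = read_summary_stats(_write(tmp_path, GOOD_LINES))
    assert len(t) == 3 and t.n_rejected == 0
    assert list(t.variant_ids) == ["rs1", "rs2", "rs3"]


@pytest.mark.parametrize("bad_line, reason_part", [
    ("rsB\t1\t500\tA\tG\t0.3\t0.1\t0\t1e-9\t50000\n", "se"),
    ("rsB\t1\t500\tA\tG\t1.2\t0.1\t0.02\t1e-9\t50000\n", "eaf"),
    ("rsB\t1\t500\tA\tG\t0.3\t0.1\t0.02\t1.5\t50000\n", "pvalue"),
    ("rsB\t1\t500\tA\tA\t0.3\t0.1\t0.02\t1e-9\t50000\n", "allele"),
    ("rsB\t1\t500\tA\tX\t0.3\t0.1\t0.02\t1e-9\t50000\n", "allele"),
])
def test_invalid_rows_rejected_with_reason(tmp_path, bad_line, reason_part):
    t = read_summary_stats(_write(tmp_path, GOOD_LINES + [bad_line]))
    assert len(t) == 3 and t.n_rejected == 1
    assert reason_part in t.rejection_log["reason"].iloc[0]


def test_hand_counted_mixed_fixture(tmp_path):
    # 3 good rows + bad eaf + bad se + duplicate id = 3 kept, 3 rejected
    lines = GOOD_LINES + [
        "rs4\t1\t4000\tA\tG\t1.2\t0.1\t0.02\t1e-9\t50000\n",
        "rs5\t1\t5000\tA\tG\t0.3\t0.1\t0\t1e-9\t50000\n",
        "rs1\t1\t1000\tA\tG\t0.30\t0.10\t0.02\t1e-9\t50000\n",
    ]
    t = read_summary_stats(_write(tmp_path, lines))
    assert len(t) == 3 and t.n_rejected == 3
    assert set(t.rejection_log["variant_id"]) == {"rs4", "rs5", "rs1"}


def test_missing_column_names_the_column(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("SNP\tCHR\tPOS\tEA\tOA\tEAF\tBETA\tP\tN\n")
    with pytest.raises(FormatError, match="SE"):
        read_summary_stats(path)


def test_all_rows_invalid_is_empty_input(tmp_path):
    path = _write(tmp_path,
                  ["rs1\t1\t1000\tA\tG\t0.3\t0.1\t0\t1e-9\t50000\n"])
    with pytest.raises(EmptyInputError):
        read_summary_stats(path)


def test_gzip_and_column_map_roundtrip(tmp_path):
    gz = tmp_path / "stats.tsv.gz"
    content = (HEADER.replace("SNP", "rsid") + GOOD_LINES[0])
    with gzip.open(gz, "wt") as fh:
        fh.write(content)
    t = read_summary_stats(gz, column_map={"rsid": "SNP"})
    assert len(t) == 1
    out = tmp_path / "rt.tsv"
    write_summary_stats(t, out)
    t2 = read_summary_stats(out)
    assert np.allclose(t2.data["beta"], t.data["beta"])


def _pair_tables(mk, exp_row, out_row):
    e = mk([dict(variant_id="rs1", pos=1000, **exp_row)])
    o = mk([dict(variant_id="rs1", pos=1000, **out_row)])
    return e, o


# rule-table oracle over allele configurations: (outcome EA/OA, eafs) ->
# expected action and sign of the returned outcome beta
RULES = [
    # direct match
    (dict(effect_allele="A", other_allele="G", beta=0.05, se=0.01, eaf=0.3),
     "kept_as_is", 0.05),
    # swapped alleles: flip sign, flip eaf
    (dict(effect_allele="G", other_allele="A", beta=0.05, se=0.01, eaf=0.3),
     "flipped", -0.05),
    # strand complement (A,G)->(T,C): same orientation
    (dict(effect_allele="T", other_allele="C", beta=0.05, se=0.01, eaf=0.3),
     "kept_as_is", 0.05),
    # complement + swap
    (dict(effect_allele="C", other_allele="T", beta=0.05, se=0.01, eaf=0.3),
     "flipped", -0.05),
    # unrelated alleles
    (dict(effect_allele="A", other_allele="C", beta=0.05, se=0.01, eaf=0.3),
     "dropped_mismatch", None),
]


@pytest.mark.parametrize("out_row, action, out_beta", RULES)
def test_harmonization_rule_table(mk_table, out_row, action, out_beta):
    e, o = _pair_tables(
        mk_table,
        dict(effect_allele="A", other_allele="G", beta=0.1, se=0.02, eaf=0.3),
        out_row)
    h = harmonize_pair(e, o)
    assert h.loc[0, "action"] == action
    if out_beta is not None:
        assert h.loc[0, "outcome_beta"] == pytest.approx(out_beta)
    if action == "flipped":
        assert h.loc[0, "outcome_eaf"] == pytest.approx(1 - out_row["eaf"])


@pytest.mark.parametrize("eaf_x, eaf_y, limit, action, sign", [
    (0.50, 0.50, 0.42, "dropped_palindromic", None),
    (0.10, 0.12, 0.42, "kept_as_is", +1),      # same side: strand resolved
    (0.10, 0.88, 0.42, "flipped", -1),          # opposite side: strand flip
    (0.45, 0.10, 0.42, "dropped_palindromic", None),  # exposure too common
])
def test_palindromic_frequency_rules(mk_table, eaf_x, eaf_y, limit, action,
                                     sign):
    e, o = _pair_tables(
        mk_table,
        dict(effect_allele="A", other_allele="T", beta=0.1, se=0.02,
             eaf=eaf_x),
        dict(effect_allele="A", other_allele="T", beta=0.05, se=0.01,
             eaf=eaf_y))
    h = harmonize_pair(e, o, palindromic_eaf_limit=limit)
    assert h.loc[0, "action"] == action
    assert bool(h.loc[0, "palindromic"]) is True
    if sign is not None:
        assert np.sign(h.loc[0, "outcome_beta"]) == sign


def test_harmonization_idempotent_and_double_flip(mk_table):
    exp = mk_table([
        dict(variant_id="rs1", pos=1000, effect_allele="A", other_allele="G",
             beta=0.1, se=0.02, eaf=0.3),
        dict(variant_id="rs2", pos=2000, effect_allele="C", other_allele="A",
             beta=-0.2, se=0.03, eaf=0.4),
    ])
    out = mk_table([
        dict(variant_id="rs1", pos=1000, effect_allele="G", other_allele="A",
             beta=0.05, se=0.01, eaf=0.7),
        dict(variant_id="rs2", pos=2000, effect_allele="C", other_allele="A",
             beta=0.08, se=0.01, eaf=0.4),
    ])
    h1 = harmonize_pair(exp, out)
    # rebuild the outcome on the exposure's alleles and harmonize again
    realigned = out.data.copy()
    realigned.loc[:, ["effect_allele", "other_allele"]] = \
        exp.data[["effect_allele", "other_allele"]].to_numpy()
    realigned["beta"] = h1["outcome_beta"].to_numpy()
    realigned["eaf"] = h1["outcome_eaf"].to_numpy()
    out2 = SummaryStatsTable("o", "binary", realigned)
    h2 = harmonize_pair(exp, out2)
    assert (h2["action"] == "kept_as_is").all()
    np.testing.assert_allclose(h2["outcome_beta"], h1["outcome_beta"])

    # double flip returns the original orientation
    flipped = out.data.copy()
    flipped[["effect_allele", "other_allele"]] = \
        flipped[["other_allele", "effect_allele"]].to_numpy()
    flipped["beta"] = -flipped["beta"]
    flipped["eaf"] = 1 - flipped["eaf"]
    h3 = harmonize_pair(exp, SummaryStatsTable("o", "binary", flipped))
    np.testing.assert_allclose(np.sort(h3["outcome_beta"]),
                               np.sort(h1["outcome_beta"]))


def test_count_conservation_and_empty_intersection(mk_table):
    exp = mk_table([
        dict(variant_id=f"rs{i}", pos=1000 * (i + 1), effect_allele="A",
             other_allele="T" if i % 2 else "G", beta=0.1, se=0.02,
             eaf=0.5 if i % 2 else 0.3)
        for i in range(6)])
    out = mk_table([
        dict(variant_id=f"rs{i}", pos=1000 * (i + 1), effect_allele="A",
             other_allele="T" if i % 2 else "G", beta=0.05, se=0.01,
             eaf=0.5 if i % 2 else 0.3)
        for i in range(4)])
    h = harmonize_pair(exp, out)
    assert len(h) == 4  # kept + dropped equals the intersection
    assert len(kept(h)) + (h["action"].str.startswith("dropped")).sum() == 4

    other = mk_table([dict(variant_id="zz9", pos=5, effect_allele="A",
                           other_allele="G", beta=0.1, se=0.02)])
    with pytest.raises(EmptyInputError, match="variant-id"):
        harmonize_pair(exp, other)
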
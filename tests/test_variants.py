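"""MAF reading, substitution collapsing, burdens and gene frequencies."""

import itertools

import numpy as np
import pandas as pd
import pytest

from somameth.variants import (
    GROUPS,
    CohortVariantTable,
    MafFormatError,
    collapse_substitution,
    compare_group_burden,
    per_gene_frequency,
    per_patient_burden,
    read_maf,
    write_maf,
)


def _table(rows, roster):
    cols = ["patient_id", "group", "gene", "chrom", "pos", "ref", "alt",
            "variant_type", "variant_class"]
    return CohortVariantTable(
        pd.DataFrame(rows, columns=cols),
        pd.DataFrame(roster, columns=["patient_id", "group"]),
    )


# ---------------------------------------------------------------------------
# read_maf

def test_read_maf_infers_variant_types(toy_maf):
    table = read_maf(toy_maf)
    assert list(table.variants["variant_type"]) == ["SNP", "INS", "DEL"]
    assert list(table.variants["gene"]) == ["TP53", "NEB", "OBSCN"]
    assert table.variants["pos"].dtype.kind == "i"


def test_read_maf_rejects_ref_equals_alt(tmp_path):
    p = tmp_path / "bad.maf"
    p.write_text(
        "gene\tpatient_id\tgroup\tchrom\tpos\tref\talt\n"
        "A\tPD01\tPD\tchr1\t100\tC\tT\n"
        "B\tPD01\tPD\tchr1\t200\tG\tG\n"
    )
    with pytest.raises(MafFormatError, match="line 3"):
        read_maf(p)


def test_read_maf_missing_column(tmp_path):
    p = tmp_path / "bad.maf"
    p.write_text("gene\tpatient_id\tgroup\tchrom\tpos\tref\nA\tP\tPD\tc\t1\tC\n")
    with pytest.raises(MafFormatError, match="alt"):
        read_maf(p)


def test_read_maf_unknown_group(tmp_path):
    p = tmp_path / "bad.maf"
    p.write_text(
        "gene\tpatient_id\tgroup\tchrom\tpos\tref\talt\n"
        "A\tP1\tCONTROL\tchr1\t100\tC\tT\n"
    )
    with pytest.raises(MafFormatError, match="CONTROL"):
        read_maf(p)


def test_maf_round_trip(bundle_dir, tmp_path):
    d, manifest = bundle_dir
    table = read_maf(d / manifest["files"]["maf"])
    out = tmp_path / "again.maf"
    write_maf(table, out)
    again = read_maf(out)
    pd.testing.assert_frame_equal(table.variants, again.variants)


# ---------------------------------------------------------------------------
# collapse_substitution

@pytest.mark.parametrize("ref,alt,expected", [
    ("C", "T", "C>T"),
    ("G", "A", "C>T"),
    ("T", "G", "T>G"),
    ("A", "C", "T>G"),
])
def test_collapse_examples(ref, alt, expected):
    assert collapse_substitution(ref, alt) == expected


def test_collapse_is_two_to_one_surjection():
    """All 12 ordered base pairs collapse onto 6 classes, 2 each."""
    counts = {}
    for ref, alt in itertools.permutations("ACGT", 2):
        counts.setdefault(collapse_substitution(ref, alt), []).append((ref, alt))
    assert set(counts) == {"C>A", "C>G", "C>T", "T>A", "T>C", "T>G"}
    assert all(len(v) == 2 for v in counts.values())


def test_collapse_idempotent_on_image():
    for sub in ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G"):
        ref, alt = sub.split(">")
        assert collapse_substitution(ref, alt) == sub


def test_collapse_rejects_bad_alleles():
    with pytest.raises(ValueError):
        collapse_substitution("N", "A")
    with pytest.raises(ValueError):
        collapse_substitution("C", "C")


# ---------------------------------------------------------------------------
# burdens

def test_per_patient_burden_counts_and_zero_patient():
    rows = [
        ("P1", "PD", "A", "chr1", 100, "C", "T", "SNP", "missense"),
        ("P1", "PD", "A", "chr1", 101, "G", "A", "SNP", "silent"),
        ("P1", "PD", "B", "chr1", 102, "T", "C", "SNP", "missense"),
        ("P1", "PD", "B", "chr1", 103, "A", "-", "DEL", "frame_shift_del"),
    ]
    table = _table(rows, [("P1", "PD"), ("P2", "PD")])
    s = per_patient_burden(table)
    assert s.by_type.loc["P1", ["SNP", "INS", "DEL"]].tolist() == [3, 0, 1]
    assert s.by_type.loc["P2", ["SNP", "INS", "DEL"]].tolist() == [0, 0, 0]
    # conservation: substitution classes sum to SNP count, types to total
    assert s.by_substitution.loc["P1"].sum() == s.by_type.loc["P1", "SNP"]
    assert s.by_type.loc["P1", ["SNP", "INS", "DEL"]].sum() == s.by_type.loc["P1", "total"]
    assert s.by_substitution.loc["P1", "C>T"] == 2  # C>T and G>A collapse


def test_burden_conservation_on_generated_cohort(small_cohort):
    table, _, _, _ = small_cohort
    s = per_patient_burden(table)
    assert (s.by_substitution.sum(axis=1) == s.by_type["SNP"]).all()
    assert (s.by_type[["SNP", "INS", "DEL"]].sum(axis=1) == s.by_type["total"]).all()


def test_poisson_rate_recovered_at_study_scale(default_cohort):
    """PD group mean burden lands within 3 SE of the configured 564."""
    table, _, _, _ = default_cohort
    s = per_patient_burden(table)
    pd_counts = s.by_type["total"][s.groups == "PD"]
    se = np.sqrt(564 / len(pd_counts))
    assert abs(pd_counts.mean() - 564) < 3 * se


# ---------------------------------------------------------------------------
# group comparison

def test_compare_identical_groups_p_one():
    rows = []
    for i, p in enumerate(["P1", "P2", "P3", "Q1", "Q2", "Q3"]):
        g = "PD" if p.startswith("P") else "PDDM"
        for j in range(i % 3 + 1):
            rows.append((p, g, "A", "chr1", 100 + j, "C", "T", "SNP", "missense"))
    roster = [(p, "PD" if p.startswith("P") else "PDDM")
              for p in ["P1", "P2", "P3", "Q1", "Q2", "Q3"]]
    table = _table(rows, roster)
    s = per_patient_burden(table)
    res = compare_group_burden(s, "SNP", "PD", "PDDM")
    assert res.pvalue == pytest.approx(1.0)


def test_compare_exact_separated():
    rows = []
    roster = []
    for p, g, n in [("P1", "PD", 1), ("P2", "PD", 2), ("P3", "PD", 3),
                    ("Q1", "PDDM", 4), ("Q2", "PDDM", 5), ("Q3", "PDDM", 6)]:
        roster.append((p, g))
        rows += [(p, g, "A", "chr1", 100 + i, "C", "T", "SNP", "missense")
                 for i in range(n)]
    s = per_patient_burden(_table(rows, roster))
    res = compare_group_burden(s, "SNP", "PD", "PDDM")
    assert res.pvalue == pytest.approx(0.1)


def test_compare_requires_two_patients_per_group():
    s = per_patient_burden(_table(
        [("P1", "PD", "A", "chr1", 100, "C", "T", "SNP", "missense")],
        [("P1", "PD"), ("Q1", "PDDM"), ("Q2", "PDDM")],
    ))
    with pytest.raises(ValueError):
        compare_group_burden(s, "SNP", "PD", "PDDM")


def test_compare_welch_mode_runs():
    rows, roster = [], []
    for p, g, n in [("P1", "PD", 2), ("P2", "PD", 4), ("P3", "PD", 3),
                    ("Q1", "PDDM", 8), ("Q2", "PDDM", 9), ("Q3", "PDDM", 7)]:
        roster.append((p, g))
        rows += [(p, g, "A", "chr1", 100 + i, "C", "T", "SNP", "missense")
                 for i in range(n)]
    s = per_patient_burden(_table(rows, roster))
    res = compare_group_burden(s, "SNP", "PD", "PDDM", mode="welch")
    assert res.method == "welch-t" and 0 < res.pvalue < 0.05


def test_planted_group_difference_power(small_cohort):
    """PDDM's higher configured rate is detected at the cohort scale."""
    # one large cohort at the study scale gives overwhelming separation;
    # a rank-sum on total burden must reject at alpha = 0.05 in most small
    # replicates too
    from somameth.synthetic import generate_cohort
    from tests.conftest import small_spec

    rejections = 0
    n_seeds = 50
    for seed in range(n_seeds):
        spec = small_spec(seed=seed + 100,
                          mutation_rate={"healthy": 0.0, "PD": 80.0, "PDDM": 110.0})
        table, _, _, _ = generate_cohort(spec)
        s = per_patient_burden(table)
        res = compare_group_burden(s, "total", "PD", "PDDM")
        rejections += res.pvalue <= 0.05
    assert rejections / n_seeds > 0.8


# ---------------------------------------------------------------------------
# per-gene frequency

def test_per_gene_frequency_rounding():
    # 6 of 11 carriers -> 55%; 1 of 15 -> 7%
    rows = [(f"P{i}", "PDDM", "SNX19", "chr11", 100 + i, "C", "T", "SNP", "missense")
            for i in range(6)]
    roster = [(f"P{i}", "PDDM") for i in range(11)]
    freq = per_gene_frequency(_table(rows, roster), "PDDM")
    assert freq.set_index("gene").loc["SNX19", "percent"] == 55

    rows = [("Q0", "PD", "SNX19", "chr11", 100, "C", "T", "SNP", "missense")]
    roster = [(f"Q{i}", "PD") for i in range(15)]
    freq = per_gene_frequency(_table(rows, roster), "PD")
    assert freq.set_index("gene").loc["SNX19", "percent"] == 7


def test_per_gene_frequency_deduplicates_patients():
    rows = [("P1", "PD", "A", "chr1", 100 + i, "C", "T", "SNP", "missense")
            for i in range(3)]
    freq = per_gene_frequency(_table(rows, [("P1", "PD"), ("P2", "PD")]), "PD")
    assert freq.set_index("gene").loc["A", "n_mutated_patients"] == 1
    assert freq.set_index("gene").loc["A", "percent"] == 50


def test_per_gene_frequency_nonsilent_flag():
    rows = [
        ("P1", "PD", "A", "chr1", 100, "C", "T", "SNP", "silent"),
        ("P2", "PD", "A", "chr1", 101, "C", "T", "SNP", "missense"),
    ]
    table = _table(rows, [("P1", "PD"), ("P2", "PD")])
    assert per_gene_frequency(table, "PD").iloc[0]["n_mutated_patients"] == 2
    assert per_gene_frequency(table, "PD", nonsilent_only=True).iloc[0][
        "n_mutated_patients"] == 1
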
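"""Somatic variant tables: MAF-like I/O, classification, burden, frequency.

The cohort is organised in three groups — healthy donors (the reference in
every contrast), periodontitis (PD), and periodontitis with type-2 diabetes
(PDDM).  Variant tables follow MAF conventions: tab-delimited, 1-based
inclusive coordinates, one row per somatic variant per patient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .stats import RankSumResult, rank_sum_test

GROUPS = ("healthy", "PD", "PDDM")

VARIANT_TYPES = ("SNP", "INS", "DEL")

VARIANT_CLASSES = (
    "missense",
    "nonsense",
    "silent",
    "splice_site",
    "frame_shift_ins",
    "frame_shift_del",
    "in_frame_ins",
    "in_frame_del",
    "nonstop",
    "translation_start",
    "other",
)

SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: canonical column names and the case-insensitive MAF aliases we accept
_COLUMN_ALIASES = {
    "hugo_symbol": "gene",
    "tumor_sample_barcode": "patient_id",
    "start_position": "pos",
    "chromosome": "chrom",
    "reference_allele": "ref",
    "tumor_seq_allele2": "alt",
    "variant_classification": "variant_class",
}

_REQUIRED_COLUMNS = ("patient_id", "group", "gene", "chrom", "pos", "ref", "alt")


class MafFormatError(ValueError):
    """Raised when a variant table violates the expected format."""


@dataclass
class CohortVariantTable:
    """Validated per-patient somatic variant records plus a patient roster.

    The roster may contain patients with zero variants (healthy donors
    typically contribute no somatic calls); they still count in burdens and
    frequencies.
    """

    variants: pd.DataFrame
    roster: pd.DataFrame  # columns: patient_id, group

    def __post_init__(self) -> None:
        missing = set(self.variants["patient_id"]) - set(self.roster["patient_id"])
        if missing:
            raise MafFormatError(
                f"variants reference patients absent from roster: {sorted(missing)[:5]}"
            )
        bad_groups = set(self.roster["group"]) - set(GROUPS)
        if bad_groups:
            raise MafFormatError(f"unknown group labels: {sorted(bad_groups)}")

    def patients(self, group: str | None = None) -> list[str]:
        r = self.roster
        if group is not None:
            r = r[r["group"] == group]
        return list(r["patient_id"])

    def subset(self, group: str) -> pd.DataFrame:
        pats = set(self.patients(group))
        return self.variants[self.variants["patient_id"].isin(pats)]

    def snvs(self, group: str | None = None) -> pd.DataFrame:
        df = self.variants if group is None else self.subset(group)
        return df[df["variant_type"] == "SNP"]


@dataclass
class BurdenSummary:
    """Per-patient variant counts by type, class and substitution class."""

    by_type: pd.DataFrame          # patients x VARIANT_TYPES (+ "total")
    by_class: pd.DataFrame         # patients x VARIANT_CLASSES
    by_substitution: pd.DataFrame  # patients x SUBSTITUTION_CLASSES
    groups: pd.Series              # patient -> group

    def metric(self, name: str) -> pd.Series:
        """Per-patient values for a named burden metric.

        Supported: any variant type, 'total', 'INDEL' (INS+DEL), any
        variant class, or any of the six substitution classes.
        """
        if name in self.by_type.columns:
            return self.by_type[name]
        if name == "INDEL":
            return self.by_type["INS"] + self.by_type["DEL"]
        if name in self.by_class.columns:
            return self.by_class[name]
        if name in self.by_substitution.columns:
            return self.by_substitution[name]
        raise KeyError(f"unknown burden metric {name!r}")

    def to_tidy(self) -> pd.DataFrame:
        frames = []
        for df, kind in ((self.by_type, "type"), (self.by_class, "class"),
                         (self.by_substitution, "substitution")):
            long = df.reset_index().melt(
                id_vars="patient_id", var_name="metric", value_name="count")
            long.insert(1, "group", long["patient_id"].map(self.groups))
            long.insert(2, "kind", kind)
            frames.append(long)
        return pd.concat(frames, ignore_index=True)


def collapse_substitution(ref: str, alt: str) -> str:
    """Collapse a single-base substitution onto the pyrimidine strand.

    Purine-reference substitutions are reverse-complemented so the
    reference base is C or T, yielding one of the six canonical classes.
    """
    if ref not in _COMPLEMENT or alt not in _COMPLEMENT:
        raise ValueError(f"non-ACGT allele in substitution {ref}>{alt}")
    if ref == alt:
        raise ValueError(f"ref equals alt ({ref})")
    if ref in "CT":
        return f"{ref}>{alt}"
    return f"{_COMPLEMENT[ref]}>{_COMPLEMENT[alt]}"


def _infer_variant_type(ref: str, alt: str) -> str:
    if len(ref) == 1 and len(alt) == 1 and ref != "-" and alt != "-":
        return "SNP"
    if ref == "-" or len(alt) > len(ref):
        return "INS"
    if alt == "-" or len(ref) > len(alt):
        return "DEL"
    return "other"


def read_maf(path: str | Path, roster: pd.DataFrame | None = None) -> CohortVariantTable:
    """Read a MAF-like tab-delimited variant table.

    Case-insensitive MAF column aliases (Hugo_Symbol, Tumor_Sample_Barcode,
    Start_Position, ...) are accepted.  A ``group`` column is required
    unless an explicit roster (patient_id, group) is given.  Rows violating
    the record invariants are reported with their line numbers.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    df.columns = [
        _COLUMN_ALIASES.get(c.lower(), c.lower()) for c in df.columns
    ]
    required = [c for c in _REQUIRED_COLUMNS if c != "group" or roster is None]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MafFormatError(f"{path.name}: missing required column(s) {missing}")

    df["pos"] = pd.to_numeric(df["pos"], errors="coerce")
    errors: list[str] = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        if pd.isna(row["pos"]) or row["pos"] < 1:
            errors.append(f"line {line}: invalid position {row['pos']!r}")
        if row["ref"] == row["alt"]:
            errors.append(f"line {line}: ref equals alt ({row['ref']!r})")
    if errors:
        raise MafFormatError(f"{path.name}: " + "; ".join(errors[:10]))
    df["pos"] = df["pos"].astype(int)

    if "variant_type" not in df.columns:
        df["variant_type"] = [
            _infer_variant_type(r, a) for r, a in zip(df["ref"], df["alt"])
        ]
    if "variant_class" not in df.columns:
        df["variant_class"] = "other"

    if roster is None:
        bad = sorted(set(df["group"]) - set(GROUPS))
        if bad:
            raise MafFormatError(f"{path.name}: unknown group label(s) {bad}")
        roster = (
            df[["patient_id", "group"]].drop_duplicates().reset_index(drop=True)
        )
    else:
        roster = roster[["patient_id", "group"]].copy()
        df = df.drop(columns=[c for c in ("group",) if c in df.columns])
        df = df.merge(roster, on="patient_id", how="left")
    return CohortVariantTable(df.reset_index(drop=True), roster)


def write_maf(table: CohortVariantTable, path: str | Path) -> None:
    table.variants.to_csv(path, sep="\t", index=False)


def per_patient_burden(table: CohortVariantTable) -> BurdenSummary:
    """Count variants per patient by type, class and substitution class.

    Patients in the roster with no variants receive zero rows.  Per
    patient, substitution-class counts sum to the SNP count and type
    counts sum to the total.
    """
    pats = table.roster["patient_id"]
    groups = table.roster.set_index("patient_id")["group"]
    v = table.variants

    def _pivot(col: str, categories: tuple[str, ...], frame: pd.DataFrame) -> pd.DataFrame:
        ct = pd.crosstab(frame["patient_id"], frame[col])
        ct = ct.reindex(index=pats, columns=list(categories), fill_value=0)
        ct.index.name = "patient_id"
        return ct.astype(int)

    by_type = _pivot("variant_type", VARIANT_TYPES, v)
    by_type["total"] = (
        v.groupby("patient_id").size().reindex(pats, fill_value=0).values
    )
    by_class = _pivot("variant_class", VARIANT_CLASSES, v)

    snv = v[v["variant_type"] == "SNP"].copy()
    if len(snv):
        snv["substitution"] = [
            collapse_substitution(r, a) for r, a in zip(snv["ref"], snv["alt"])
        ]
    else:
        snv["substitution"] = pd.Series(dtype=str)
    by_sub = _pivot("substitution", SUBSTITUTION_CLASSES, snv)
    return BurdenSummary(by_type, by_class, by_sub, groups)


def compare_group_burden(
    summary: BurdenSummary,
    metric: str,
    group_a: str,
    group_b: str,
    mode: str = "wilcoxon",
) -> RankSumResult:
    """Two-sided between-group test on a per-patient burden metric.

    The primary test is the Wilcoxon rank-sum (the study's stated policy
    for two-group comparisons); ``mode='welch'`` switches to a Welch
    t-test for compatibility with t-test figure labels.
    """
    values = summary.metric(metric)
    xa = values[summary.groups.reindex(values.index) == group_a].to_numpy(float)
    xb = values[summary.groups.reindex(values.index) == group_b].to_numpy(float)
    if xa.size < 2 or xb.size < 2:
        raise ValueError(
            f"both groups need >=2 patients (got {xa.size} {group_a}, {xb.size} {group_b})"
        )
    if mode == "wilcoxon":
        return rank_sum_test(xa, xb)
    if mode == "welch":
        from scipy import stats as sps

        t, p = sps.ttest_ind(xa, xb, equal_var=False)
        return RankSumResult(float(t), float(p), float(np.median(xa)),
                             float(np.median(xb)), "welch-t")
    raise ValueError(f"unknown mode {mode!r}")


def per_gene_frequency(
    table: CohortVariantTable, group: str, nonsilent_only: bool = False
) -> pd.DataFrame:
    """Fraction of a group's patients carrying >=1 variant per gene.

    A patient counts once per gene regardless of variant multiplicity.
    Percent is rounded half away from zero to an integer, matching how
    oncoplot margins are usually printed.
    """
    pats = table.patients(group)
    if not pats:
        raise ValueError(f"group {group!r} has no patients in roster")
    df = table.subset(group)
    if nonsilent_only:
        df = df[~df["variant_class"].isin(["silent"])]
    carriers = df.groupby("gene")["patient_id"].nunique()
    n = len(pats)
    out = pd.DataFrame({
        "gene": carriers.index,
        "n_mutated_patients": carriers.values,
        "fraction": carriers.values / n,
    })
    out["percent"] = [int(math.floor(100.0 * f + 0.5)) for f in out["fraction"]]
    return out.sort_values(
        ["n_mutated_patients", "gene"], ascending=[False, True]
    ).reset_index(drop=True)
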
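"""Somatic interactions, pathway burden scoring, and over-representation.

Pairwise gene co-occurrence / mutual exclusivity is tested on a binary
gene x patient carrier matrix with Fisher's exact test (odds ratio > 1
labels co-occurrence, < 1 exclusivity), BH-adjusted across pairs.
Pathway burden is the fraction of a group's patients carrying at least
one qualifying variant in any member gene; "hypo intensity" is the mean
hypo-dmCpG count per member gene.  Gene-set over-representation uses the
upper-tail hypergeometric test against an explicit gene universe.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .stats import bh_adjust, fisher_exact_2x2, hypergeom_sf
from .variants import CohortVariantTable, collapse_substitution


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read gene sets from a GMT file (name, description, members...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


def gene_patient_matrix(
    table: CohortVariantTable, group: str, qualifying: str = "any"
) -> pd.DataFrame:
    """Binary gene x patient matrix (1 = patient carries >=1 qualifying variant).

    ``qualifying`` is 'any' or 'C>T-only' (restrict to C>T single-base
    substitutions on the pyrimidine strand).
    """
    pats = table.patients(group)
    df = table.subset(group)
    df = _qualify(df, qualifying)
    mat = pd.crosstab(df["gene"], df["patient_id"]).clip(upper=1)
    return mat.reindex(columns=pats, fill_value=0).astype(int)


def _qualify(df: pd.DataFrame, qualifying: str) -> pd.DataFrame:
    if qualifying == "any":
        return df
    if qualifying == "C>T-only":
        snv = df[df["variant_type"] == "SNP"]
        keep = [
            collapse_substitution(r, a) == "C>T"
            for r, a in zip(snv["ref"], snv["alt"])
        ]
        return snv[keep]
    raise ValueError(f"unknown qualifying rule {qualifying!r}")


def pairwise_interaction(
    matrix: pd.DataFrame, min_carriers: int = 3
) -> pd.DataFrame:
    """Fisher-exact co-occurrence / mutual exclusivity for gene pairs.

    Genes with fewer than ``min_carriers`` carriers, or trivially mutated
    in all patients, are excluded (listed nowhere in the output; counts in
    the attrs).  For each remaining pair, the 2x2 patient table (both /
    only A / only B / neither) gives a two-sided Fisher p and a sample
    odds ratio with Haldane correction for zero cells; BH is applied
    across all tested pairs.
    """
    carriers = matrix.sum(axis=1)
    n = matrix.shape[1]
    eligible = matrix.index[(carriers >= min_carriers) & (carriers < n)]
    excluded = [g for g in matrix.index if g not in set(eligible)]
    if len(eligible) < 2:
        raise ValueError(
            f"need >=2 genes with >= {min_carriers} carriers (have {len(eligible)})"
        )
    rows = []
    m = matrix.loc[eligible].to_numpy(bool)
    for (i, ga), (j, gb) in combinations(enumerate(eligible), 2):
        a = int(np.sum(m[i] & m[j]))
        b = int(np.sum(m[i] & ~m[j]))
        c = int(np.sum(~m[i] & m[j]))
        d = int(np.sum(~m[i] & ~m[j]))
        odds, p = fisher_exact_2x2([[a, b], [c, d]])
        rows.append((ga, gb, a, b, c, d, odds, p))
    out = pd.DataFrame(
        rows,
        columns=["gene_a", "gene_b", "n_both", "n_a_only", "n_b_only",
                 "n_neither", "odds_ratio", "p_value"],
    )
    out["q_value"] = bh_adjust(out["p_value"])
    out["label"] = np.where(out["odds_ratio"] > 1, "co-occurrence", "exclusivity")
    out.loc[out["odds_ratio"] == 1, "label"] = "none"
    out.attrs["n_excluded_genes"] = len(excluded)
    return out.sort_values("p_value", ignore_index=True)


@dataclass
class PathwayScore:
    pathway: str
    members_found: list[str]
    patient_burden_fraction: float
    percent: int
    per_gene_percent: dict[str, int]
    mean_hypo_intensity: float | None = None


def pathway_burden(
    table: CohortVariantTable,
    gene_set: list[str],
    group: str,
    qualifying: str = "any",
    name: str = "pathway",
) -> PathwayScore:
    """Fraction of a group's patients with >=1 qualifying variant in the set."""
    if not gene_set:
        raise ValueError("gene set is empty")
    pats = table.patients(group)
    df = _qualify(table.subset(group), qualifying)
    df = df[df["gene"].isin(gene_set)]
    members = sorted(df["gene"].unique())
    carriers = df["patient_id"].nunique()
    frac = carriers / len(pats)
    per_gene = {
        g: int(math.floor(100.0 * df[df["gene"] == g]["patient_id"].nunique()
                          / len(pats) + 0.5))
        for g in members
    }
    return PathwayScore(
        pathway=name,
        members_found=members,
        patient_burden_fraction=frac,
        percent=int(math.floor(100.0 * frac + 0.5)),
        per_gene_percent=per_gene,
    )


def pathway_hypo_intensity(
    integration_table: pd.DataFrame,
    gene_set: list[str],
    include_absent: bool = True,
) -> float:
    """Mean hypo-dmCpG count per member gene.

    Member genes absent from the integration table count as zero by
    default; with ``include_absent=False`` the mean is over present
    members only (an empty intersection is an error).
    """
    if not gene_set:
        raise ValueError("gene set is empty")
    counts = integration_table["n_dm_hypo"]
    present = [g for g in gene_set if g in counts.index]
    if include_absent:
        vals = [float(counts.get(g, 0)) for g in gene_set]
    else:
        if not present:
            raise ValueError("no member gene present in the integration table")
        vals = [float(counts[g]) for g in present]
    return float(np.mean(vals))


def ora_enrichment(
    hit_genes: list[str],
    gene_sets: dict[str, list[str]],
    universe: list[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of hit genes in each gene set.

    Sets are intersected with the universe; the p-value is the upper tail
    P(overlap >= k).  Output columns: set, n_set, k_overlap, expected,
    p_value, q_value, sorted by q then p.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty gene universe")
    hits = set(hit_genes)
    if not hits:
        raise ValueError("empty hit-gene list")
    stray = hits - universe_set
    if stray:
        raise ValueError(
            f"hit genes outside the universe: {sorted(stray)[:5]}"
        )
    n_u = len(universe_set)
    n_h = len(hits)
    rows = []
    for name, members in gene_sets.items():
        mem = set(members) & universe_set
        k = len(mem & hits)
        expected = n_h * len(mem) / n_u
        p = hypergeom_sf(k, n_u, len(mem), n_h)
        rows.append((name, len(mem), k, expected, p))
    out = pd.DataFrame(
        rows, columns=["set", "n_set", "k_overlap", "expected", "p_value"]
    )
    out["q_value"] = bh_adjust(out["p_value"])
    return out.sort_values(["q_value", "p_value"], ignore_index=True)
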
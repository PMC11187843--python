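"""Gene-level integration of C>T substitution burden with dmCpG counts.

For each gene the table joins the number of C>T substitutions observed in
a disease group (aggregated across its patients) with the number of
differentially methylated probes mapped to the gene, split by direction.
On top of that sit the Pearson correlation between C>T burden and dmCpG
count, a paired test for an excess of hypomethylation over
hypermethylation in mutated genes, and the promoter "joint hit" list:
genes carrying both a C>T substitution and a hypo dmCpG in the promoter
window (TSS1500 through 1st exon).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .methylation import PROMOTER_FEATURES, ProbeAnnotation
from .stats import SignedRankResult, signed_rank_test
from .variants import CohortVariantTable, collapse_substitution


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    pvalue: float
    n: int
    stratum: str


def _per_gene_ct_counts(variants: CohortVariantTable, group: str) -> pd.Series:
    snv = variants.snvs(group)
    if not len(snv):
        return pd.Series(dtype=int)
    subs = [collapse_substitution(r, a) for r, a in zip(snv["ref"], snv["alt"])]
    ct = snv[[s == "C>T" for s in subs]]
    return ct.groupby("gene").size()


def build_integration_table(
    variants: CohortVariantTable,
    dm: pd.DataFrame,
    ann: ProbeAnnotation,
    group: str,
) -> pd.DataFrame:
    """One row per gene seen in the variants or the annotated dm table.

    Columns: n_ct (C>T substitutions in the group), n_dm_total, n_dm_hyper,
    n_dm_hypo, n_promoter_hypo, promoter_hypo_flag, joint_hit_flag.
    Multi-gene probes contribute to every listed gene; genes absent from a
    source are zero-filled.
    """
    ct_counts = _per_gene_ct_counts(variants, group)

    called = dm[dm["call"] != "none"]
    shared = called.index.intersection(ann.table.index)
    rows = []
    for probe in shared:
        genes = [g for g in str(ann.table.at[probe, "genes"] or "").split(";") if g]
        feature = ann.table.at[probe, "feature"]
        call = called.at[probe, "call"]
        for gene in genes:
            rows.append((gene, call, feature))
    if rows:
        probe_df = pd.DataFrame(rows, columns=["gene", "call", "feature"])
        hyper = probe_df[probe_df["call"] == "hyper"].groupby("gene").size()
        hypo = probe_df[probe_df["call"] == "hypo"].groupby("gene").size()
        prom_hypo = (
            probe_df[(probe_df["call"] == "hypo")
                     & probe_df["feature"].isin(PROMOTER_FEATURES)]
            .groupby("gene").size()
        )
    else:
        hyper = hypo = prom_hypo = pd.Series(dtype=int)

    mutated_genes = set(variants.subset(group)["gene"].unique())
    genes = sorted(
        mutated_genes | set(ct_counts.index) | set(hyper.index) | set(hypo.index)
    )
    out = pd.DataFrame(index=pd.Index(genes, name="gene"))
    out["n_ct"] = ct_counts.reindex(genes, fill_value=0).astype(int)
    out["n_dm_hyper"] = hyper.reindex(genes, fill_value=0).astype(int)
    out["n_dm_hypo"] = hypo.reindex(genes, fill_value=0).astype(int)
    out["n_dm_total"] = out["n_dm_hyper"] + out["n_dm_hypo"]
    out["n_promoter_hypo"] = prom_hypo.reindex(genes, fill_value=0).astype(int)
    out["promoter_hypo_flag"] = out["n_promoter_hypo"] >= 1
    out["joint_hit_flag"] = (out["n_ct"] >= 1) & out["promoter_hypo_flag"]
    return out


_STRATUM_COLUMN = {
    "all_dm": "n_dm_total",
    "hyper": "n_dm_hyper",
    "hypo": "n_dm_hypo",
}


def correlate_ct_dm(
    table: pd.DataFrame,
    stratum: str = "all_dm",
    all_genes: bool = False,
    dm_column: str | None = None,
) -> CorrelationResult:
    """Pearson correlation of per-gene C>T count with a dmCpG count stratum.

    By default the gene universe is restricted to genes with at least one
    C>T substitution or one dmCpG (the margins that actually appear on a
    burden-vs-methylation scatter); ``all_genes=True`` keeps zero rows.
    ``dm_column`` overrides the stratum's count column, e.g. to correlate
    against nominally hypomethylated probe counts.  The p-value is the
    usual two-sided t transform of r on n-2 degrees of freedom.
    """
    col = dm_column if dm_column is not None else _STRATUM_COLUMN[stratum]
    sub = table if all_genes else table[(table["n_ct"] >= 1) | (table[col] >= 1)]
    x = sub["n_ct"].to_numpy(float)
    y = sub[col].to_numpy(float)
    if x.size < 3:
        raise ValueError("correlation requires >=3 genes")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: zero variance in a margin")
    res = sps.pearsonr(x, y)
    return CorrelationResult(float(res.statistic), float(res.pvalue),
                             int(x.size), stratum)


def hypo_vs_hyper_excess(
    table: pd.DataFrame, zero_method: str = "wilcox"
) -> SignedRankResult:
    """Excess of hypo over hyper dmCpGs in genes that carry C>T substitutions.

    Two-sided Wilcoxon signed-rank on the per-gene differences
    (n_dm_hypo - n_dm_hyper), restricted to genes with >=1 C>T.  Zero
    differences are dropped by default (``zero_method='pratt'`` keeps
    them); if every difference is zero the result is degenerate with
    p = 1.
    """
    mutated = table[table["n_ct"] >= 1]
    if len(mutated) < 5:
        raise ValueError("excess test requires >=5 genes with a C>T substitution")
    diffs = (mutated["n_dm_hypo"] - mutated["n_dm_hyper"]).to_numpy(float)
    return signed_rank_test(diffs, zero_method=zero_method)


def promoter_joint_hits(table: pd.DataFrame) -> list[str]:
    """Genes with both a C>T substitution and a promoter hypo dmCpG.

    Sorted by C>T count, then hypo dmCpG count (both descending), then
    gene name ascending.
    """
    hits = table[table["joint_hit_flag"]].reset_index()
    ordered = hits.sort_values(
        ["n_ct", "n_dm_hypo", "gene"], ascending=[False, False, True]
    )
    return list(ordered["gene"])
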
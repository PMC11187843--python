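"""EPIC-style methylation: probe filtering, dmCpG calling, annotation.

Inputs are normalised beta values (methylation fraction in [0,1]) for
probes x samples, with a sample->group map.  Differential methylation is
called per probe against the healthy reference with a two-sided Welch
t-test, Benjamini-Hochberg adjustment across all tested probes, and a
joint threshold: adjusted p <= 0.05 AND |delta beta| >= 0.2 (delta beta is
the disease-minus-reference mean difference).  Probes are stratified by
CpG-island relation (island / shore / shelf / open sea, 2 kb and 4 kb
bands) and by gene-feature group (TSS1500 ... 3'UTR, IGR for intergenic).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust

ISLAND_RELATIONS = ("Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea")

FEATURES = ("TSS1500", "TSS200", "5'UTR", "1stExon", "Body", "3'UTR", "IGR")

PROMOTER_FEATURES = ("TSS1500", "TSS200", "5'UTR", "1stExon")

SHORE_BP = 2000
SHELF_BP = 4000


@dataclass
class BetaMatrix:
    """Beta values (probes x samples) with a sample->group map."""

    betas: pd.DataFrame
    groups: pd.Series  # index: sample id, values: group label

    def __post_init__(self) -> None:
        missing = set(self.betas.columns) - set(self.groups.index)
        if missing:
            raise ValueError(
                f"samples without a group label: {sorted(missing)[:5]}"
            )
        vals = self.betas.to_numpy(float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("beta values must lie in [0, 1]")

    def samples(self, group: str) -> list[str]:
        return [s for s in self.betas.columns if self.groups[s] == group]


@dataclass
class FilterReport:
    n_input: int
    n_removed_detection_p: int
    n_removed_beads: int
    n_kept: int


@dataclass
class ProbeAnnotation:
    """Per-probe genomic annotation: position, island relation, genes, feature.

    ``genes`` is a semicolon-joined symbol list (empty for intergenic
    probes); ``feature`` is IGR exactly when no gene is listed.
    """

    table: pd.DataFrame  # index: probe id; columns chrom, pos, island_relation, genes, feature

    def __post_init__(self) -> None:
        t = self.table
        bad_rel = set(t["island_relation"]) - set(ISLAND_RELATIONS)
        if bad_rel:
            raise ValueError(f"unknown island relation(s): {sorted(bad_rel)}")
        bad_feat = set(t["feature"]) - set(FEATURES)
        if bad_feat:
            raise ValueError(f"unknown feature(s): {sorted(bad_feat)}")
        empty = t["genes"].fillna("") == ""
        igr = t["feature"] == "IGR"
        if (empty != igr).any():
            off = t.index[(empty != igr)][:3].tolist()
            raise ValueError(f"feature IGR must coincide with empty gene list "
                             f"(offenders: {off})")

    def gene_lists(self) -> pd.Series:
        return self.table["genes"].fillna("").apply(
            lambda s: [g for g in s.split(";") if g]
        )


def filter_probes(
    bm: BetaMatrix,
    detection_p: pd.DataFrame | None = None,
    bead_counts: pd.DataFrame | None = None,
    detp_frac: float | None = None,
    bead_frac: float = 0.05,
) -> tuple[BetaMatrix, FilterReport]:
    """Exclude unreliable probes before differential testing.

    A probe is dropped if its detection p-value is >= 0.01 in any sample
    (``detp_frac`` relaxes this to a fraction-of-samples rule), or if it
    has fewer than three beads in ``bead_frac`` (default 5%, boundary
    inclusive) or more of the samples.  With no auxiliary matrices the
    filter is the identity.
    """
    for name, aux in (("detection_p", detection_p), ("bead_counts", bead_counts)):
        if aux is None:
            continue
        if not aux.index.equals(bm.betas.index) or not aux.columns.equals(bm.betas.columns):
            bad_idx = aux.index.symmetric_difference(bm.betas.index)
            bad_col = aux.columns.symmetric_difference(bm.betas.columns)
            offender = (list(bad_idx) + list(bad_col) + ["<order>"])[0]
            raise ValueError(
                f"{name} matrix index mismatch with beta matrix "
                f"(first offending id: {offender!r})"
            )

    n_input = len(bm.betas)
    drop_detp = pd.Series(False, index=bm.betas.index)
    drop_beads = pd.Series(False, index=bm.betas.index)
    if detection_p is not None:
        fail = detection_p >= 0.01
        if detp_frac is None:
            drop_detp = fail.any(axis=1)
        else:
            drop_detp = fail.mean(axis=1) >= detp_frac
    if bead_counts is not None:
        drop_beads = (bead_counts < 3).mean(axis=1) >= bead_frac

    keep = ~(drop_detp | drop_beads)
    report = FilterReport(
        n_input=n_input,
        n_removed_detection_p=int(drop_detp.sum()),
        n_removed_beads=int((drop_beads & ~drop_detp).sum()),
        n_kept=int(keep.sum()),
    )
    return BetaMatrix(bm.betas.loc[keep], bm.groups), report


def dm_test(
    bm: BetaMatrix,
    disease_group: str,
    reference_group: str = "healthy",
    delta_threshold: float = 0.2,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-probe Welch two-sample t-test of disease vs reference betas.

    Returns a table with per-group means, delta beta (disease minus
    reference), t statistic, raw and BH-adjusted p, and the dmCpG call:
    hyper when delta beta >= +threshold, hypo when <= -threshold, each
    requiring adjusted p <= alpha; none otherwise.  Probes with zero
    variance in both groups and equal means get p = 1 by convention and
    are flagged in the ``degenerate`` column.
    """
    dis = bm.samples(disease_group)
    ref = bm.samples(reference_group)
    if len(dis) < 2 or len(ref) < 2:
        raise ValueError(
            f"need >=2 samples per group ({disease_group}: {len(dis)}, "
            f"{reference_group}: {len(ref)})"
        )
    x = bm.betas[dis].to_numpy(float)
    y = bm.betas[ref].to_numpy(float)
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("NaN betas are not allowed after filtering")

    mean_d = x.mean(axis=1)
    mean_r = y.mean(axis=1)
    delta = mean_d - mean_r

    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat, p_raw = sps.ttest_ind(x, y, axis=1, equal_var=False)
        degenerate = ~np.isfinite(p_raw)
        # zero variance in both groups: equal means -> no evidence, p = 1;
        # unequal means with zero variance -> infinitely strong separation
        p_raw = np.where(degenerate & (delta == 0), 1.0, p_raw)
        p_raw = np.where(degenerate & (delta != 0), 0.0, p_raw)
        t_stat = np.where(np.isfinite(t_stat), t_stat,
                          np.where(delta == 0, 0.0, np.sign(delta) * np.inf))

    q = bh_adjust(p_raw)
    call = np.full(len(p_raw), "none", dtype=object)
    call[(q <= alpha) & (delta >= delta_threshold)] = "hyper"
    call[(q <= alpha) & (delta <= -delta_threshold)] = "hypo"

    return pd.DataFrame(
        {
            f"mean_{disease_group}": mean_d,
            f"mean_{reference_group}": mean_r,
            "delta_beta": delta,
            "t_stat": t_stat,
            "p_value": p_raw,
            "q_value": q,
            "call": call,
            "degenerate": degenerate,
        },
        index=bm.betas.index,
    )


def annotate_island_relation(
    pos: int, islands: list[tuple[int, int]]
) -> str:
    """Classify a 1-based position against CpG islands on its chromosome.

    ``islands`` are 0-based half-open, non-overlapping intervals.  Inside
    an island -> Island; within 2,000 bp of the nearest island edge ->
    N_Shore (5' side, lower coordinates) or S_Shore; 2,001-4,000 bp ->
    N_Shelf / S_Shelf; beyond -> OpenSea.
    """
    if not islands:
        return "OpenSea"
    ordered = sorted(islands)
    for (s1, e1), (s2, e2) in zip(ordered, ordered[1:]):
        if s2 < e1:
            raise ValueError(f"overlapping islands ({s1},{e1}) and ({s2},{e2})")
    p0 = pos - 1
    best: tuple[int, str] | None = None
    for start, end in ordered:
        if start <= p0 < end:
            return "Island"
        if p0 < start:
            d = start - p0
            side = "N"
        else:
            d = p0 - (end - 1)
            side = "S"
        if d <= SHORE_BP:
            rel = f"{side}_Shore"
        elif d <= SHELF_BP:
            rel = f"{side}_Shelf"
        else:
            continue
        if best is None or d < best[0]:
            best = (d, rel)
    return best[1] if best else "OpenSea"


def read_islands_bed(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """Read CpG-island intervals from a BED file (0-based half-open)."""
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            out.setdefault(chrom, []).append((int(start), int(end)))
    return out


@dataclass
class DmSummary:
    by_island_relation: pd.DataFrame  # island_relation x {hyper, hypo}
    by_feature: pd.DataFrame          # feature x {hyper, hypo}
    totals: pd.Series                 # hyper, hypo, total
    n_unannotated: int


def summarize_dm(dm: pd.DataFrame, ann: ProbeAnnotation) -> DmSummary:
    """Tabulate hyper/hypo dmCpG counts by island relation and gene feature.

    Probes absent from the annotation are counted under ``n_unannotated``
    and excluded from the stratified tables (not from the totals).
    """
    called = dm[dm["call"] != "none"]
    known = called.index.intersection(ann.table.index)
    n_unann = len(called) - len(known)
    sub = called.loc[known]
    annot = ann.table.loc[known]

    def _tab(col: str, categories: tuple[str, ...]) -> pd.DataFrame:
        ct = pd.crosstab(annot[col], sub["call"])
        ct = ct.reindex(index=list(categories), columns=["hyper", "hypo"],
                        fill_value=0)
        return ct.astype(int)

    totals = pd.Series(
        {
            "hyper": int((called["call"] == "hyper").sum()),
            "hypo": int((called["call"] == "hypo").sum()),
            "total": int(len(called)),
        }
    )
    return DmSummary(
        by_island_relation=_tab("island_relation", ISLAND_RELATIONS),
        by_feature=_tab("feature", FEATURES),
        totals=totals,
        n_unannotated=n_unann,
    )


def read_beta_matrix(betas_path: str | Path, sample_sheet_path: str | Path) -> BetaMatrix:
    betas = pd.read_csv(betas_path, sep="\t", index_col=0)
    sheet = pd.read_csv(sample_sheet_path, sep="\t")
    groups = sheet.set_index("sample_id")["group"]
    return BetaMatrix(betas, groups)


def read_probe_annotation(path: str | Path) -> ProbeAnnotation:
    df = pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False)
    return ProbeAnnotation(df)
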
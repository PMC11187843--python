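"""Probe filtering, dmCpG calling, island annotation, summaries."""

import numpy as np
import pandas as pd
import pytest

from somameth.methylation import (
    BetaMatrix,
    ProbeAnnotation,
    annotate_island_relation,
    dm_test,
    filter_probes,
    summarize_dm,
)
from somameth.synthetic import generate_cohort
from tests.conftest import small_spec


def _bm(betas_dict, groups_dict, probes=None):
    betas = pd.DataFrame(betas_dict)
    if probes is not None:
        betas.index = probes
    return BetaMatrix(betas, pd.Series(groups_dict))


# ---------------------------------------------------------------------------
# filtering

def _aux(bm, values):
    return pd.DataFrame(values, index=bm.betas.index, columns=bm.betas.columns)


def test_detection_p_any_sample_rule():
    bm = _bm({"s1": [0.5, 0.5], "s2": [0.5, 0.5]},
             {"s1": "healthy", "s2": "PD"}, probes=["p1", "p2"])
    detp = _aux(bm, [[0.001, 0.02], [0.001, 0.001]])
    kept, report = filter_probes(bm, detection_p=detp)
    assert list(kept.betas.index) == ["p2"]
    assert report.n_removed_detection_p == 1


def test_bead_rule_boundary_inclusive():
    # 40 samples; bead < 3 in exactly 2 samples = 5% -> removed
    samples = {f"s{i}": "PD" for i in range(40)}
    betas = pd.DataFrame(
        np.full((2, 40), 0.5), index=["p1", "p2"], columns=list(samples))
    bm = BetaMatrix(betas, pd.Series(samples))
    beads = _aux(bm, np.full((2, 40), 10))
    beads.iloc[0, :2] = 2
    beads.iloc[1, 0] = 2  # only 2.5% of samples -> kept
    kept, report = filter_probes(bm, bead_counts=beads)
    assert list(kept.betas.index) == ["p2"]
    assert report.n_removed_beads == 1


def test_no_auxiliary_matrices_identity():
    bm = _bm({"s1": [0.1, 0.9], "s2": [0.2, 0.8]},
             {"s1": "healthy", "s2": "PD"})
    kept, report = filter_probes(bm)
    assert kept.betas.equals(bm.betas)
    assert report.n_removed_detection_p == report.n_removed_beads == 0


def test_index_mismatch_names_offender():
    bm = _bm({"s1": [0.5], "s2": [0.5]}, {"s1": "healthy", "s2": "PD"},
             probes=["p1"])
    detp = pd.DataFrame([[0.001, 0.001]], index=["pX"], columns=["s1", "s2"])
    with pytest.raises(ValueError, match="p1|pX"):
        filter_probes(bm, detection_p=detp)


# ---------------------------------------------------------------------------
# dm test

def _welch_oracle(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
    t = (x.mean() - y.mean()) / np.sqrt(vx + vy)
    df = (vx + vy) ** 2 / (vx ** 2 / (len(x) - 1) + vy ** 2 / (len(y) - 1))
    from scipy import stats as sps
    return t, 2 * sps.t.sf(abs(t), df)


def test_dm_test_hand_case():
    disease = [0.31, 0.29, 0.30, 0.32]
    reference = [0.72, 0.70, 0.69, 0.71]
    groups = {f"d{i}": "PD" for i in range(4)} | {f"h{i}": "healthy" for i in range(4)}
    betas = pd.DataFrame(
        [disease + reference], index=["p1"],
        columns=[f"d{i}" for i in range(4)] + [f"h{i}" for i in range(4)])
    dm = dm_test(BetaMatrix(betas, pd.Series(groups)), "PD")
    t, p = _welch_oracle(disease, reference)
    assert dm.loc["p1", "delta_beta"] == pytest.approx(-0.40, abs=1e-9)
    assert dm.loc["p1", "t_stat"] == pytest.approx(t)
    assert dm.loc["p1", "p_value"] == pytest.approx(p)
    assert dm.loc["p1", "call"] == "hypo"


def test_small_delta_not_called_despite_significance():
    rng = np.random.default_rng(0)
    n = 20
    disease = 0.50 + rng.normal(0, 0.004, n)
    reference = 0.65 + rng.normal(0, 0.004, n)
    cols = [f"d{i}" for i in range(n)] + [f"h{i}" for i in range(n)]
    groups = {c: ("PD" if c.startswith("d") else "healthy") for c in cols}
    betas = pd.DataFrame([list(disease) + list(reference)], index=["p1"],
                         columns=cols)
    dm = dm_test(BetaMatrix(betas, pd.Series(groups)), "PD")
    assert dm.loc["p1", "q_value"] < 1e-6
    assert abs(dm.loc["p1", "delta_beta"]) < 0.2
    assert dm.loc["p1", "call"] == "none"


def test_zero_variance_equal_means_flagged_p_one():
    cols = ["d0", "d1", "h0", "h1"]
    groups = {"d0": "PD", "d1": "PD", "h0": "healthy", "h1": "healthy"}
    betas = pd.DataFrame([[0.4, 0.4, 0.4, 0.4]], index=["p1"], columns=cols)
    dm = dm_test(BetaMatrix(betas, pd.Series(groups)), "PD")
    assert dm.loc["p1", "degenerate"]
    assert dm.loc["p1", "p_value"] == 1.0
    assert dm.loc["p1", "call"] == "none"


def test_dm_requires_two_samples_per_group():
    groups = {"d0": "PD", "h0": "healthy", "h1": "healthy"}
    betas = pd.DataFrame([[0.4, 0.5, 0.6]], index=["p1"], columns=list(groups))
    with pytest.raises(ValueError, match=">=2 samples"):
        dm_test(BetaMatrix(betas, pd.Series(groups)), "PD")


def test_type_one_error_calibration_under_null():
    """Raw p <= 0.05 in ~5% of probes; joint BH+delta rule calls ~none."""
    rng = np.random.default_rng(7)
    n_probes, n = 10_000, 10
    mu = 0.5
    nu = 100.0
    cols = [f"d{i}" for i in range(n)] + [f"h{i}" for i in range(n)]
    groups = {c: ("PD" if c.startswith("d") else "healthy") for c in cols}
    betas = pd.DataFrame(rng.beta(mu * nu, (1 - mu) * nu, (n_probes, 2 * n)),
                         columns=cols)
    dm = dm_test(BetaMatrix(betas, pd.Series(groups)), "PD")
    frac = (dm["p_value"] <= 0.05).mean()
    assert abs(frac - 0.05) < 0.01
    assert (dm["call"] != "none").sum() <= 2


def test_power_planted_delta_detected():
    """Planted |delta beta| = 0.3 at n = 10/10 is called in >= 95% of probes."""
    rng = np.random.default_rng(8)
    n_probes, n_shift, n = 2000, 200, 10
    nu = 120.0  # per-sample beta SD <= 0.05 at these means
    base = np.full(n_probes, 0.75)
    shifted = base.copy()
    shifted[:n_shift] = 0.45
    cols = [f"d{i}" for i in range(n)] + [f"h{i}" for i in range(n)]
    groups = {c: ("PD" if c.startswith("d") else "healthy") for c in cols}
    data = np.empty((n_probes, 2 * n))
    for j in range(n):
        data[:, j] = rng.beta(shifted * nu, (1 - shifted) * nu)
        data[:, n + j] = rng.beta(base * nu, (1 - base) * nu)
    dm = dm_test(BetaMatrix(pd.DataFrame(data, columns=cols),
                            pd.Series(groups)), "PD")
    detected = (dm["call"].iloc[:n_shift] == "hypo").mean()
    assert detected >= 0.95
    false = (dm["call"].iloc[n_shift:] != "none").mean()
    assert false < 0.01


# ---------------------------------------------------------------------------
# island relation

ISLANDS = [(10_000, 11_000)]


@pytest.mark.parametrize("pos0,expected", [
    (10_500, "Island"),            # inside
    (10_000, "Island"),            # inclusive start
    (10_999, "Island"),            # last island base
    (10_000 - 1_500, "N_Shore"),   # 1,500 bp before the start
    (10_000 - 2_000, "N_Shore"),   # shore boundary inclusive
    (10_000 - 2_001, "N_Shelf"),
    (10_000 - 4_000, "N_Shelf"),
    (10_000 - 4_001, "OpenSea"),
    (11_000, "S_Shore"),           # first base past the end
    (11_000 + 1_999, "S_Shore"),
    (11_000 + 3_999, "S_Shelf"),   # 4,000 bp past the last island base
    (11_000 + 4_000, "OpenSea"),   # 4,001 bp past: beyond the shelf band
])
def test_island_relation_distance_bands(pos0, expected):
    assert annotate_island_relation(pos0 + 1, ISLANDS) == expected


def test_overlapping_islands_rejected():
    with pytest.raises(ValueError, match="overlap"):
        annotate_island_relation(5, [(0, 10), (5, 20)])


def test_no_islands_open_sea():
    assert annotate_island_relation(100, []) == "OpenSea"


# ---------------------------------------------------------------------------
# summaries

def _annotation(rows):
    df = pd.DataFrame(
        rows, columns=["probe_id", "chrom", "pos", "island_relation",
                       "genes", "feature"]).set_index("probe_id")
    return ProbeAnnotation(df)


def test_summary_all_none_is_zero():
    ann = _annotation([("p1", "chr1", 100, "Island", "A", "TSS200")])
    dm = pd.DataFrame({"call": ["none"]}, index=["p1"])
    s = summarize_dm(dm, ann)
    assert s.totals["total"] == 0
    assert (s.by_island_relation.values == 0).all()


def test_summary_conservation_and_unannotated():
    ann = _annotation([
        ("p1", "chr1", 100, "Island", "A", "TSS200"),
        ("p2", "chr1", 200, "OpenSea", "A", "Body"),
    ])
    dm = pd.DataFrame({"call": ["hyper", "hypo", "hypo"]},
                      index=["p1", "p2", "p3"])
    s = summarize_dm(dm, ann)
    assert s.totals["hyper"] + s.totals["hypo"] == s.totals["total"] == 3
    assert s.n_unannotated == 1
    assert s.by_feature.loc["TSS200", "hyper"] == 1
    assert s.by_feature.loc["Body", "hypo"] == 1


def test_promoter_only_planting_concentrates_in_promoter_features():
    """With body probes absent from genes, every hypo call sits in the
    TSS1500/TSS200/5'UTR/1stExon feature window."""
    from somameth.synthetic import GeneModel

    spec = small_spec(seed=21)
    spec.gene_models = [
        GeneModel(g.symbol, g.length_bp, 3, 0) for g in spec.gene_models
    ]
    spec.hyper_background_frac = 0.0
    table, betas, ann, gt = generate_cohort(spec)
    dm = dm_test(betas, "PD")
    s = summarize_dm(dm, ann)
    promoter = ["TSS1500", "TSS200", "5'UTR", "1stExon"]
    assert s.by_feature.loc[promoter, "hypo"].sum() == s.totals["hypo"] > 0
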
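"""Synthetic three-group cohort generator with planted ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, for a cohort of healthy donors, periodontitis (PD) patients and
periodontitis + type-2 diabetes (PDDM) patients:

* per-patient somatic variant counts are Poisson with group-specific
  means (defaults on the scale of the real cohorts, several hundred
  variants per patient);
* variants land in genes with probability proportional to gene length,
  and SNV substitution classes and trinucleotide contexts are drawn from
  a per-group mixture over a signature catalog;
* array-style beta values are beta-distributed around probe-specific
  baselines drawn from a bimodal (methylated/unmethylated) mixture;
  probes in genes that carry planted C>T substitutions are shifted
  downward in the disease group, with the per-probe shift probability
  increasing with the gene's C>T count and a tunable coupling strength.

Everything is driven by a single integer seed; identical specs produce
bit-identical outputs.  The ground-truth object records what was planted
so recovery tests can compare against the analysis output.

The generative model is a stand-in with the right moments and coupling
direction, not an estimate of any real cohort.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .methylation import BetaMatrix, ProbeAnnotation, annotate_island_relation
from .signatures import CONTEXT_96, SignatureCatalog, synthetic_catalog, write_catalog
from .variants import _COMPLEMENT, CohortVariantTable, GROUPS

DISEASE_GROUPS = ("PD", "PDDM")


class ConfigurationError(ValueError):
    """Raised when a cohort specification is internally inconsistent."""


@dataclass(frozen=True)
class GeneModel:
    symbol: str
    length_bp: int
    n_promoter_probes: int
    n_body_probes: int


def default_gene_models(n_genes: int = 120) -> list[GeneModel]:
    """Deterministic gene panel: log-spaced lengths, varied probe counts."""
    lengths = np.unique(
        np.geomspace(5_000, 200_000, n_genes).astype(int)
    )
    while len(lengths) < n_genes:  # pad in case of collisions
        lengths = np.append(lengths, lengths[-1] + 1000)
    return [
        GeneModel(
            symbol=f"G{i + 1:03d}",
            length_bp=int(lengths[i]),
            n_promoter_probes=2 + (i % 3),       # 2-4
            n_body_probes=3 + (i % 5),           # 3-7
        )
        for i in range(n_genes)
    ]


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort.

    Defaults mirror the study design: 10 healthy / 15 PD / 11 PDDM
    patients, mean somatic burdens of 564 (PD) and 589 (PDDM) variants
    per patient, a mismatch-repair-like signature mixture in PD and a
    deamination-like mixture in PDDM, and hypomethylation shifts of mean
    magnitude 0.3 coupled to per-gene C>T burden.
    """

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"healthy": 10, "PD": 15, "PDDM": 11}
    )
    gene_models: list[GeneModel] = field(default_factory=default_gene_models)
    mutation_rate: dict[str, float] = field(
        default_factory=lambda: {"healthy": 0.0, "PD": 564.0, "PDDM": 589.0}
    )
    signature_weights: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "healthy": {"SBS5": 1.0},
            "PD": {"SBS6": 0.7, "SBS5": 0.3},
            "PDDM": {"SBS1": 0.7, "SBS5": 0.3},
        }
    )
    ct_meth_coupling: float = 1.0
    delta_beta_effect: float = 0.3
    beta_dispersion: float = 100.0
    hyper_background_frac: float = 0.02
    n_igr_probes: int = 200
    seed: int = 0

    def validate(self, catalog: SignatureCatalog) -> None:
        if not self.gene_models:
            raise ConfigurationError("spec has zero genes")
        n_probes = sum(
            g.n_promoter_probes + g.n_body_probes for g in self.gene_models
        ) + self.n_igr_probes
        if n_probes == 0:
            raise ConfigurationError("spec has zero probes")
        bad_groups = set(self.n_per_group) - set(GROUPS)
        if bad_groups:
            raise ConfigurationError(f"unknown group(s): {sorted(bad_groups)}")
        for g, n in self.n_per_group.items():
            if n <= 0:
                raise ConfigurationError(f"group {g} has non-positive size {n}")
        if not 0.0 <= self.delta_beta_effect <= 1.0:
            raise ConfigurationError("delta_beta_effect must be in [0, 1]")
        if not 0.0 <= self.hyper_background_frac <= 1.0:
            raise ConfigurationError("hyper_background_frac must be in [0, 1]")
        if self.ct_meth_coupling < 0:
            raise ConfigurationError("ct_meth_coupling must be >= 0")
        if self.beta_dispersion <= 0:
            raise ConfigurationError("beta_dispersion must be > 0")
        if self.ct_meth_coupling > 0 and not any(
            g in self.n_per_group for g in DISEASE_GROUPS
        ):
            raise ConfigurationError(
                "mutation-methylation coupling requires at least one disease group"
            )
        for g in self.n_per_group:
            w = self.signature_weights.get(g, {})
            if self.mutation_rate.get(g, 0.0) > 0:
                if not w:
                    raise ConfigurationError(f"group {g} has no signature weights")
                if abs(sum(w.values()) - 1.0) > 1e-9:
                    raise ConfigurationError(
                        f"signature weights for {g} must sum to 1"
                    )
                unknown = set(w) - set(catalog.names)
                if unknown:
                    raise ConfigurationError(
                        f"signature(s) not in catalog for {g}: {sorted(unknown)}"
                    )


@dataclass
class GroundTruth:
    """What the generator planted, for recovery tests."""

    ct_counts: pd.DataFrame           # genes x disease groups: planted C>T counts
    shifts: pd.DataFrame              # probes x disease groups: planted beta shift
    coupling: float
    generating_signature: dict[str, str]  # group -> top-weight signature name
    promoter_joint_hits: dict[str, list[str]]  # group -> planted joint-hit genes


# ---------------------------------------------------------------------------
# genomic layout

_CHROMS = ("chr1", "chr2", "chr3", "chr4")
_GENE_GAP = 200_000
_ISLAND_BEFORE_TSS = 300   # island spans [tss-300, tss+700) around the start
_ISLAND_AFTER_TSS = 700


def _layout(spec: CohortSpec):
    """Assign gene coordinates, promoter islands, and probe positions."""
    offsets = {c: 1_000_000 for c in _CHROMS}
    genes = []
    islands: dict[str, list[tuple[int, int]]] = {c: [] for c in _CHROMS}
    probe_rows = []
    pid = 0
    for i, gm in enumerate(spec.gene_models):
        chrom = _CHROMS[i % len(_CHROMS)]
        start = offsets[chrom]  # 0-based gene start (TSS)
        offsets[chrom] = start + gm.length_bp + _GENE_GAP
        genes.append((gm.symbol, chrom, start, gm.length_bp))
        islands[chrom].append(
            (start - _ISLAND_BEFORE_TSS, start + _ISLAND_AFTER_TSS)
        )
        prom_features = ["TSS1500", "TSS200", "1stExon", "5'UTR"]
        for j in range(gm.n_promoter_probes):
            pos0 = start - 200 + 250 * j  # inside/near the promoter island
            probe_rows.append(
                (f"cg{pid:06d}", chrom, pos0 + 1, gm.symbol,
                 prom_features[j % len(prom_features)])
            )
            pid += 1
        for j in range(gm.n_body_probes):
            frac = (j + 1) / (gm.n_body_probes + 1)
            pos0 = start + int(gm.length_bp * max(frac, 0.1))
            probe_rows.append(
                (f"cg{pid:06d}", chrom, pos0 + 1, gm.symbol, "Body")
            )
            pid += 1
    # intergenic probes midway between consecutive genes on each chromosome
    per_chrom = max(1, spec.n_igr_probes // len(_CHROMS))
    for c in _CHROMS:
        top = offsets[c]
        for j in range(per_chrom):
            if pid - sum(g.n_promoter_probes + g.n_body_probes
                         for g in spec.gene_models) >= spec.n_igr_probes:
                break
            pos0 = 500_000 + int(j * (top / per_chrom))
            probe_rows.append((f"cg{pid:06d}", c, pos0 + 1, "", "IGR"))
            pid += 1

    ann = pd.DataFrame(
        probe_rows, columns=["probe_id", "chrom", "pos", "genes", "feature"]
    ).set_index("probe_id")
    ann["island_relation"] = [
        annotate_island_relation(int(p), islands[c])
        for c, p in zip(ann["chrom"], ann["pos"])
    ]
    # IGR probes that happen to sit near a promoter island would violate the
    # feature/gene invariant downstream interpretation; keep them but their
    # island relation is whatever the distance rules say.
    ann = ann[["chrom", "pos", "island_relation", "genes", "feature"]]
    gene_df = pd.DataFrame(
        genes, columns=["gene", "chrom", "start", "length"]
    ).set_index("gene")
    return gene_df, islands, ann


# ---------------------------------------------------------------------------
# variant generation

_SNP_CLASSES = np.array(["missense", "silent", "nonsense", "splice_site", "other"])
_SNP_CLASS_P = np.array([0.55, 0.30, 0.05, 0.05, 0.05])
_TYPE_P = {"SNP": 0.90, "INS": 0.05, "DEL": 0.05}

_PYR_REF = np.array([lab[2] for lab in CONTEXT_96])
_PYR_ALT = np.array([lab[4] for lab in CONTEXT_96])
_FIVE = np.array([lab[0] for lab in CONTEXT_96])
_THREE = np.array([lab[6] for lab in CONTEXT_96])
_COMP = np.vectorize(_COMPLEMENT.get)


def _group_patients(spec: CohortSpec) -> dict[str, list[str]]:
    out = {}
    for g in GROUPS:
        if g in spec.n_per_group:
            prefix = {"healthy": "H", "PD": "PD", "PDDM": "DM"}[g]
            out[g] = [f"{prefix}{i + 1:02d}" for i in range(spec.n_per_group[g])]
    return out


def _draw_variants(
    spec: CohortSpec,
    catalog: SignatureCatalog,
    gene_df: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    lengths = gene_df["length"].to_numpy(float)
    gene_p = lengths / lengths.sum()
    gene_names = gene_df.index.to_numpy()
    frames = []
    for group, patients in _group_patients(spec).items():
        rate = float(spec.mutation_rate.get(group, 0.0))
        counts = rng.poisson(rate, len(patients))
        n = int(counts.sum())
        if n == 0:
            continue
        pat = np.repeat(np.array(patients, dtype=object), counts)
        gidx = rng.choice(len(gene_names), size=n, p=gene_p)
        starts = gene_df["start"].to_numpy()[gidx]
        glens = lengths[gidx].astype(int)
        pos = starts + 1 + rng.integers(0, glens, size=n)  # 1-based
        chrom = gene_df["chrom"].to_numpy()[gidx]
        vtype = rng.choice(
            np.array(list(_TYPE_P)), size=n, p=np.array(list(_TYPE_P.values()))
        )
        is_snp = vtype == "SNP"

        ref = np.empty(n, dtype=object)
        alt = np.empty(n, dtype=object)
        vclass = np.empty(n, dtype=object)
        ctx = np.empty(n, dtype=object)
        ctx[:] = ""

        n_snp = int(is_snp.sum())
        if n_snp:
            mix = np.zeros(96)
            for name, w in spec.signature_weights[group].items():
                mix += w * catalog.vector(name)
            mix = mix / mix.sum()
            bins = rng.choice(96, size=n_snp, p=mix)
            pyr_ref, pyr_alt = _PYR_REF[bins], _PYR_ALT[bins]
            five, three = _FIVE[bins], _THREE[bins]
            flip = rng.random(n_snp) < 0.5  # report on the purine strand half the time
            s_ref = np.where(flip, _COMP(pyr_ref), pyr_ref)
            s_alt = np.where(flip, _COMP(pyr_alt), pyr_alt)
            s_ctx = np.where(
                flip,
                [_rc3(f, r, t) for f, r, t in zip(five, pyr_ref, three)],
                [f + r + t for f, r, t in zip(five, pyr_ref, three)],
            )
            ref[is_snp] = s_ref
            alt[is_snp] = s_alt
            ctx[is_snp] = s_ctx
            vclass[is_snp] = rng.choice(_SNP_CLASSES, size=n_snp, p=_SNP_CLASS_P)

        for kind, ref_val in (("INS", "-"), ("DEL", None)):
            mask = vtype == kind
            k = int(mask.sum())
            if not k:
                continue
            base = rng.choice(np.array(list("ACGT")), size=k)
            if kind == "INS":
                ref[mask] = "-"
                alt[mask] = base
                vclass[mask] = rng.choice(
                    np.array(["frame_shift_ins", "in_frame_ins"]), size=k,
                    p=np.array([0.8, 0.2]),
                )
            else:
                ref[mask] = base
                alt[mask] = "-"
                vclass[mask] = rng.choice(
                    np.array(["frame_shift_del", "in_frame_del"]), size=k,
                    p=np.array([0.8, 0.2]),
                )

        frames.append(pd.DataFrame({
            "patient_id": pat,
            "group": group,
            "gene": gene_names[gidx],
            "chrom": chrom,
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "variant_type": vtype,
            "variant_class": vclass,
            "ref_context": ctx,
        }))
    if not frames:
        cols = ["patient_id", "group", "gene", "chrom", "pos", "ref", "alt",
                "variant_type", "variant_class", "ref_context"]
        return pd.DataFrame(columns=cols)
    return pd.concat(frames, ignore_index=True)


def _rc3(five: str, mid: str, three: str) -> str:
    return _COMPLEMENT[three] + _COMPLEMENT[mid] + _COMPLEMENT[five]


# ---------------------------------------------------------------------------
# methylation generation

def _plant_shifts(
    spec: CohortSpec,
    ct_counts: pd.DataFrame,
    ann: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Decide the planted beta shift of each probe in each disease group.

    Negative entries are mutation-coupled hypomethylation: for a gene
    with planted C>T count c, each of its probes is shifted down with
    probability 1 - exp(-coupling * c / s), where s is three times the
    group's mean positive per-gene count.  The saturating form keeps the
    shift probability in a responsive range across the coupling grid
    while staying exactly zero at zero coupling.  Positive entries are a
    small uncoupled hypermethylation background (``hyper_background_frac``
    of gene probes, uniform across genes), mimicking the disease-wide
    hyper dmCpGs real cohorts show without tying them to mutations.
    """
    disease = [g for g in DISEASE_GROUPS if g in spec.n_per_group]
    shifts = pd.DataFrame(0.0, index=ann.index, columns=disease)
    gene_of_probe = ann["genes"]
    for group in disease:
        c = ct_counts[group] if group in ct_counts.columns else None
        if c is not None and spec.ct_meth_coupling > 0 and c.sum() > 0:
            positive = c[c > 0]
            scale = 3.0 * max(1.0, float(positive.mean()))
            p_gene = 1.0 - np.exp(-spec.ct_meth_coupling * c / scale)
            for probe, gene in gene_of_probe.items():
                if not gene:
                    continue
                p = float(p_gene.get(gene, 0.0))
                if p > 0 and rng.random() < p:
                    shifts.at[probe, group] = -spec.delta_beta_effect
        if spec.hyper_background_frac > 0:
            for probe, gene in gene_of_probe.items():
                if not gene or shifts.at[probe, group] != 0:
                    continue
                if rng.random() < spec.hyper_background_frac:
                    shifts.at[probe, group] = spec.delta_beta_effect
    return shifts


def _draw_betas(
    spec: CohortSpec,
    ann: pd.DataFrame,
    shifts: pd.DataFrame,
    patients: dict[str, list[str]],
    rng: np.random.Generator,
) -> BetaMatrix:
    n_probes = len(ann)
    shifted_down = (shifts < 0).any(axis=1).to_numpy()
    shifted_up = ((shifts > 0).any(axis=1) & ~(shifts < 0).any(axis=1)).to_numpy()
    # bimodal baseline: unmethylated and methylated modes
    low = rng.beta(2.0, 12.0, n_probes)
    high = rng.beta(12.0, 2.0, n_probes)
    pick_high = rng.random(n_probes) < 0.6
    baseline = np.where(pick_high, high, low)
    # planted shifts must stay observable within [0, 1]: downward-shifted
    # probes start from the methylated range, upward-shifted from the
    # unmethylated range
    baseline = np.where(shifted_down, rng.uniform(0.65, 0.9, n_probes), baseline)
    baseline = np.where(shifted_up, rng.uniform(0.1, 0.35, n_probes), baseline)

    sample_ids = [p for g in patients for p in patients[g]]
    group_of = {p: g for g in patients for p in patients[g]}
    nu = spec.beta_dispersion
    cols = {}
    for s in sample_ids:
        g = group_of[s]
        mu = baseline.copy()
        if g in shifts.columns:
            mu = mu + shifts[g].to_numpy()
        mu = np.clip(mu, 0.02, 0.98)
        cols[s] = rng.beta(mu * nu, (1.0 - mu) * nu)
    betas = pd.DataFrame(cols, index=ann.index)
    groups = pd.Series({p: group_of[p] for p in sample_ids})
    return BetaMatrix(betas, groups)


# ---------------------------------------------------------------------------
# public API

def generate_cohort(
    spec: CohortSpec, catalog: SignatureCatalog | None = None
) -> tuple[CohortVariantTable, BetaMatrix, ProbeAnnotation, GroundTruth]:
    """Generate a full synthetic cohort from a spec.

    Returns the variant table, the beta matrix (all groups), the probe
    annotation, and the planted ground truth.  Identical specs (including
    the seed) produce bit-identical outputs.
    """
    catalog = catalog or synthetic_catalog()
    spec.validate(catalog)
    rng = np.random.default_rng(spec.seed)

    gene_df, _islands, ann = _layout(spec)
    variants = _draw_variants(spec, catalog, gene_df, rng)

    # planted C>T counts per gene per disease group (pyrimidine-strand class)
    disease = [g for g in DISEASE_GROUPS if g in spec.n_per_group]
    ct_counts = pd.DataFrame(0, index=gene_df.index, columns=disease)
    if len(variants):
        snv = variants[variants["variant_type"] == "SNP"]
        is_ct = snv["ref_context"].str.len().eq(3) & (
            ((snv["ref"] == "C") & (snv["alt"] == "T"))
            | ((snv["ref"] == "G") & (snv["alt"] == "A"))
        )
        for group in disease:
            sub = snv[is_ct & (snv["group"] == group)]
            counts = sub.groupby("gene").size()
            ct_counts[group] = counts.reindex(gene_df.index, fill_value=0).astype(int)

    shifts = _plant_shifts(spec, ct_counts, ann, rng)
    patients = _group_patients(spec)
    betas = _draw_betas(spec, ann, shifts, patients, rng)

    roster = pd.DataFrame(
        [(p, g) for g in patients for p in patients[g]],
        columns=["patient_id", "group"],
    )
    table = CohortVariantTable(variants, roster)

    joint_hits = {}
    promoter_mask = ann["feature"].isin(["TSS1500", "TSS200", "5'UTR", "1stExon"])
    for group in disease:
        shifted_prom_genes = set(
            ann.loc[promoter_mask & (shifts[group] < 0), "genes"]
        )
        mutated = set(ct_counts.index[ct_counts[group] > 0])
        joint_hits[group] = sorted(shifted_prom_genes & mutated)

    gt = GroundTruth(
        ct_counts=ct_counts,
        shifts=shifts,
        coupling=spec.ct_meth_coupling,
        generating_signature={
            g: max(w, key=w.get)
            for g, w in spec.signature_weights.items()
            if g in spec.n_per_group and spec.mutation_rate.get(g, 0) > 0
        },
        promoter_joint_hits=joint_hits,
    )
    return table, betas, ProbeAnnotation(ann), gt


def default_gene_sets(spec: CohortSpec) -> dict[str, list[str]]:
    """Deterministic gene-set partition over the spec's gene panel.

    Membership is interleaved across the length-sorted panel so each set
    spans the gene-length range instead of capturing only short or only
    long genes.
    """
    symbols = [g.symbol for g in spec.gene_models]
    names = ["FC_GAMMA_PHAGOCYTOSIS", "PI3K_AKT", "ECM_RECEPTOR", "T2DM"]
    sets = {name: symbols[i::6] for i, name in enumerate(names)}
    return {k: v for k, v in sets.items() if v}


def write_fixture_bundle(spec: CohortSpec, out_dir: str | Path) -> dict:
    """Emit a cohort as the pipeline's file formats plus a manifest.

    Writes the MAF-like variant table, beta matrix, sample sheet, probe
    annotation, gene sets (GMT) and signature catalog, then a
    ``manifest.json`` listing the files and the seed.  Identical specs
    produce byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    catalog = synthetic_catalog()
    table, betas, ann, _gt = generate_cohort(spec, catalog)

    files = {
        "maf": "variants.maf.tsv",
        "betas": "betas.tsv",
        "sample_sheet": "sample_sheet.tsv",
        "annotation": "probe_annotation.tsv",
        "gene_sets": "gene_sets.gmt",
        "catalog": "signature_catalog.tsv",
    }
    try:
        table.variants.to_csv(out / files["maf"], sep="\t", index=False)
        betas.betas.round(6).to_csv(out / files["betas"], sep="\t")
        betas.groups.rename("group").rename_axis("sample_id").reset_index().to_csv(
            out / files["sample_sheet"], sep="\t", index=False
        )
        ann.table.rename_axis("probe_id").to_csv(out / files["annotation"], sep="\t")
        from .enrichment import write_gmt

        write_gmt(default_gene_sets(spec), out / files["gene_sets"])
        write_catalog(catalog, out / files["catalog"])
    except OSError as exc:
        raise OSError(f"failed writing fixture file: {exc.filename}") from exc

    manifest = {
        "seed": spec.seed,
        "files": files,
        "n_per_group": spec.n_per_group,
        "mutation_rate": spec.mutation_rate,
        "ct_meth_coupling": spec.ct_meth_coupling,
        "delta_beta_effect": spec.delta_beta_effect,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
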
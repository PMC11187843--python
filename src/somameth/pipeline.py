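"""End-to-end orchestration: config, stage graph, machine-readable report.

Stage order mirrors the analysis narrative: variant burden ->
spectra/signature matching -> dmCpG calling -> gene-level integration ->
interactions/pathways -> over-representation.  A stage whose inputs are
missing records an explicit skip (with the reason) instead of failing the
run; a stage that errors marks the run failed and downstream dependents
skip.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Optional

import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import __version__
from .enrichment import (
    gene_patient_matrix,
    ora_enrichment,
    pairwise_interaction,
    pathway_burden,
    pathway_hypo_intensity,
    read_gmt,
)
from .integration import (
    build_integration_table,
    correlate_ct_dm,
    hypo_vs_hyper_excess,
    promoter_joint_hits,
)
from .methylation import (
    dm_test,
    filter_probes,
    read_beta_matrix,
    read_probe_annotation,
    summarize_dm,
)
from .signatures import FastaLookup, best_match, build_spectrum, read_catalog
from .variants import compare_group_burden, per_gene_frequency, per_patient_burden, read_maf

log = logging.getLogger("somameth")


class Thresholds(BaseModel):
    detection_p: float = 0.01
    detp_frac: Optional[float] = None  # None = any-sample rule
    delta_beta: float = 0.2
    adjusted_p: float = 0.05
    min_carriers: int = 3


class RunConfig(BaseModel):
    """Validated pipeline configuration (paths + contrasts + thresholds)."""

    maf: Optional[str] = None
    betas: Optional[str] = None
    sample_sheet: Optional[str] = None
    annotation: Optional[str] = None
    detection_p: Optional[str] = None
    bead_counts: Optional[str] = None
    catalog: Optional[str] = None
    gene_sets: Optional[str] = None
    fasta: Optional[str] = None
    reference_group: str = "healthy"
    disease_groups: list[str] = Field(default_factory=lambda: ["PD", "PDDM"])
    thresholds: Thresholds = Field(default_factory=Thresholds)
    out_dir: str = "somameth_out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls.model_validate(data)
        for name in ("maf", "betas", "sample_sheet", "annotation", "catalog",
                     "gene_sets", "fasta", "detection_p", "bead_counts"):
            p = getattr(cfg, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config path {name} does not exist: {p}")
        return cfg

    @classmethod
    def from_bundle(cls, bundle_dir: str | Path, **overrides: Any) -> "RunConfig":
        """Build a config from a fixture-bundle manifest directory."""
        bundle = Path(bundle_dir)
        with open(bundle / "manifest.json") as fh:
            manifest = json.load(fh)
        files = manifest["files"]
        data = {
            "maf": str(bundle / files["maf"]),
            "betas": str(bundle / files["betas"]),
            "sample_sheet": str(bundle / files["sample_sheet"]),
            "annotation": str(bundle / files["annotation"]),
            "catalog": str(bundle / files["catalog"]),
            "gene_sets": str(bundle / files["gene_sets"]),
            "seed": manifest.get("seed", 0),
        }
        data.update(overrides)
        return cls.model_validate(data)


class StageRecord(BaseModel):
    stage: str
    status: str  # ok | skipped | failed
    reason: Optional[str] = None
    tables: list[str] = Field(default_factory=list)
    metrics: dict[str, Any] = Field(default_factory=dict)


class RunReport(BaseModel):
    """Machine-readable pipeline report: one record per stage + provenance."""

    version: str
    config_hash: str
    seed: int
    stages: list[StageRecord]
    warnings: list[str] = Field(default_factory=list)

    def stage(self, name: str) -> StageRecord:
        for s in self.stages:
            if s.stage == name:
                return s
        raise KeyError(name)


def _config_hash(config: RunConfig) -> str:
    payload = config.model_dump()
    payload.pop("out_dir", None)  # output location is not an analytic input
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()
    ).hexdigest()[:16]


def _write_table(df: pd.DataFrame, out_dir: Path, name: str) -> str:
    path = out_dir / f"{name}.tsv"
    df.to_csv(path, sep="\t")
    return path.name


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all stages defined by the config; see module docstring."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    th = config.thresholds
    stages: list[StageRecord] = []
    warnings: list[str] = []

    def skip(name: str, reason: str) -> None:
        log.info("stage %s skipped: %s", name, reason)
        stages.append(StageRecord(stage=name, status="skipped", reason=reason))

    def fail(name: str, exc: Exception) -> None:
        log.error("stage %s failed: %s", name, exc)
        stages.append(StageRecord(stage=name, status="failed", reason=str(exc)))

    # --- variants / burden -------------------------------------------------
    table = None
    if config.maf is None:
        skip("burden", "no variant table configured")
    else:
      try:
        roster = None
        if config.sample_sheet:
            sheet = pd.read_csv(config.sample_sheet, sep="\t")
            roster = sheet.rename(columns={"sample_id": "patient_id"})
        table = read_maf(config.maf, roster=roster)
        summary = per_patient_burden(table)
        tables = [_write_table(summary.to_tidy().set_index("patient_id"),
                               out_dir, "burden")]
        metrics: dict[str, Any] = {}
        for group in config.disease_groups:
            vals = summary.by_type["total"][
                summary.groups.reindex(summary.by_type.index) == group]
            if len(vals):
                metrics[f"mean_total_{group}"] = float(vals.mean())
        pairs = [(a, b) for i, a in enumerate(config.disease_groups)
                 for b in config.disease_groups[i + 1:]]
        for a, b in pairs:
            for metric in ("SNP", "missense", "C>T", "INDEL", "total"):
                try:
                    res = compare_group_burden(summary, metric, a, b)
                except (ValueError, KeyError) as exc:
                    warnings.append(f"burden test {metric} {a} vs {b}: {exc}")
                    continue
                metrics[f"p_{metric}_{a}_vs_{b}"] = res.pvalue
        for group in config.disease_groups:
            try:
                freq = per_gene_frequency(table, group)
            except ValueError as exc:
                warnings.append(f"gene frequency {group}: {exc}")
                continue
            tables.append(_write_table(freq.set_index("gene"), out_dir,
                                       f"gene_frequency_{group}"))
        stages.append(StageRecord(stage="burden", status="ok", tables=tables,
                                  metrics=metrics))
      except Exception as exc:  # stage failure: dependents will skip
        fail("burden", exc)
        table = None

    # --- spectra and signature matching ------------------------------------
    spectra = {}
    if table is None:
        skip("spectra", "no variant table")
    else:
      try:
        lookup = FastaLookup(config.fasta) if config.fasta else None
        tables, metrics = [], {}
        for group in config.disease_groups:
            try:
                spec = build_spectrum(table, group, reference_lookup=lookup)
            except ValueError as exc:
                warnings.append(f"spectrum {group}: {exc}")
                continue
            spectra[group] = spec
            tables.append(_write_table(spec.to_frame().set_index("context"),
                                       out_dir, f"spectrum_{group}"))
            metrics[f"n_snv_{group}"] = spec.total
            metrics[f"n_context_skipped_{group}"] = spec.n_skipped
        stages.append(StageRecord(stage="spectra", status="ok", tables=tables,
                                  metrics=metrics))
      except Exception as exc:
        fail("spectra", exc)
        spectra = {}

    if not spectra:
        skip("signature_match", "no spectra available")
    elif config.catalog is None:
        skip("signature_match", "no signature catalog configured")
    else:
      try:
        catalog = read_catalog(config.catalog)
        tables, metrics = [], {}
        for group, spec in spectra.items():
            ranked = best_match(spec, catalog)
            tables.append(_write_table(ranked.set_index("signature"), out_dir,
                                       f"signature_match_{group}"))
            metrics[f"top_signature_{group}"] = str(ranked["signature"][0])
            metrics[f"top_cosine_{group}"] = float(ranked["cosine"][0])
        stages.append(StageRecord(stage="signature_match", status="ok",
                                  tables=tables, metrics=metrics))
      except Exception as exc:
        fail("signature_match", exc)

    # --- dmCpG calling ------------------------------------------------------
    dm_tables: dict[str, pd.DataFrame] = {}
    ann = None
    if config.betas is None or config.sample_sheet is None:
        skip("dmcpg", "no beta matrix / sample sheet configured")
    else:
      try:
        bm = read_beta_matrix(config.betas, config.sample_sheet)
        detp = (pd.read_csv(config.detection_p, sep="\t", index_col=0)
                if config.detection_p else None)
        beads = (pd.read_csv(config.bead_counts, sep="\t", index_col=0)
                 if config.bead_counts else None)
        bm, filt = filter_probes(bm, detp, beads, detp_frac=th.detp_frac)
        if config.annotation:
            ann = read_probe_annotation(config.annotation)
        tables, metrics = [], {}
        metrics["n_probes_removed_detection_p"] = filt.n_removed_detection_p
        metrics["n_probes_removed_beads"] = filt.n_removed_beads
        metrics["n_probes_tested"] = filt.n_kept
        for group in config.disease_groups:
            try:
                dm = dm_test(bm, group, config.reference_group,
                             delta_threshold=th.delta_beta, alpha=th.adjusted_p)
            except ValueError as exc:
                warnings.append(f"dm test {group}: {exc}")
                continue
            dm_tables[group] = dm
            tables.append(_write_table(dm, out_dir, f"dmcpg_{group}"))
            metrics[f"n_dmcpg_{group}"] = int((dm["call"] != "none").sum())
            metrics[f"n_hyper_{group}"] = int((dm["call"] == "hyper").sum())
            metrics[f"n_hypo_{group}"] = int((dm["call"] == "hypo").sum())
            if ann is not None:
                summ = summarize_dm(dm, ann)
                tables.append(_write_table(summ.by_island_relation, out_dir,
                                           f"dm_island_{group}"))
                tables.append(_write_table(summ.by_feature, out_dir,
                                           f"dm_feature_{group}"))
        stages.append(StageRecord(stage="dmcpg", status="ok", tables=tables,
                                  metrics=metrics))
      except Exception as exc:
        fail("dmcpg", exc)
        dm_tables = {}
        ann = None

    # --- integration --------------------------------------------------------
    integration_tables: dict[str, pd.DataFrame] = {}
    if table is None or not dm_tables or ann is None:
        skip("integration", "requires variants, dm results and annotation")
    else:
      try:
        tables, metrics = [], {}
        for group, dm in dm_tables.items():
            it = build_integration_table(table, dm, ann, group)
            integration_tables[group] = it
            tables.append(_write_table(it, out_dir, f"integration_{group}"))
            for stratum in ("all_dm", "hyper", "hypo"):
                try:
                    res = correlate_ct_dm(it, stratum)
                except ValueError as exc:
                    warnings.append(f"correlation {group}/{stratum}: {exc}")
                    continue
                metrics[f"r_{stratum}_{group}"] = res.r
                metrics[f"p_{stratum}_{group}"] = res.pvalue
            try:
                ex = hypo_vs_hyper_excess(it)
                metrics[f"p_hypo_excess_{group}"] = ex.pvalue
            except ValueError as exc:
                warnings.append(f"hypo excess {group}: {exc}")
            hits = promoter_joint_hits(it)
            metrics[f"n_joint_hits_{group}"] = len(hits)
            tables.append(_write_table(
                it.loc[hits], out_dir, f"joint_hits_{group}"))
        stages.append(StageRecord(stage="integration", status="ok",
                                  tables=tables, metrics=metrics))
      except Exception as exc:
        fail("integration", exc)
        integration_tables = {}

    # --- interactions and pathways ------------------------------------------
    if table is None:
        skip("interactions", "no variant table")
    else:
      try:
        tables, metrics = [], {}
        for group in config.disease_groups:
            try:
                gpm = gene_patient_matrix(table, group)
                inter = pairwise_interaction(gpm, min_carriers=th.min_carriers)
            except ValueError as exc:
                warnings.append(f"interactions {group}: {exc}")
                continue
            tables.append(_write_table(inter.set_index(["gene_a", "gene_b"]),
                                       out_dir, f"interactions_{group}"))
            metrics[f"n_pairs_{group}"] = len(inter)
            metrics[f"n_significant_pairs_{group}"] = int(
                (inter["q_value"] <= 0.05).sum())
        stages.append(StageRecord(stage="interactions", status="ok",
                                  tables=tables, metrics=metrics))
      except Exception as exc:
        fail("interactions", exc)

    if table is None or config.gene_sets is None:
        skip("pathways", "requires variants and gene sets")
    else:
      try:
        sets = read_gmt(config.gene_sets)
        tables, metrics = [], {}
        rows = []
        for group in config.disease_groups:
            for name, members in sets.items():
                score = pathway_burden(table, members, group,
                                       qualifying="C>T-only", name=name)
                intensity = None
                if group in integration_tables:
                    intensity = pathway_hypo_intensity(
                        integration_tables[group], members)
                rows.append((group, name, score.patient_burden_fraction,
                             score.percent, intensity))
        path_df = pd.DataFrame(rows, columns=[
            "group", "pathway", "burden_fraction", "burden_percent",
            "mean_hypo_intensity"]).set_index(["group", "pathway"])
        tables.append(_write_table(path_df, out_dir, "pathway_scores"))
        stages.append(StageRecord(stage="pathways", status="ok", tables=tables,
                                  metrics=metrics))
      except Exception as exc:
        fail("pathways", exc)

    if not integration_tables or config.gene_sets is None:
        skip("enrichment", "requires integration results and gene sets")
    else:
      try:
        sets = read_gmt(config.gene_sets)
        tables, metrics = [], {}
        for group, it in integration_tables.items():
            universe = list(it.index)
            hits = list(it.index[(it["n_ct"] >= 1) & (it["n_dm_hypo"] >= 1)])
            if not hits:
                warnings.append(f"enrichment {group}: no joint C>T+hypo genes")
                continue
            ora = ora_enrichment(hits, sets, universe)
            tables.append(_write_table(ora.set_index("set"), out_dir,
                                       f"enrichment_{group}"))
            metrics[f"top_set_{group}"] = str(ora["set"][0])
        stages.append(StageRecord(stage="enrichment", status="ok",
                                  tables=tables, metrics=metrics))
      except Exception as exc:
        fail("enrichment", exc)

    report = RunReport(
        version=__version__,
        config_hash=_config_hash(config),
        seed=config.seed,
        stages=stages,
        warnings=warnings,
    )
    with open(out_dir / "report.json", "w") as fh:
        fh.write(report.model_dump_json(indent=2))
    return report
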
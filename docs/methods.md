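# Methods

## Cohort model and analysis contrasts

The package assumes a three-group design: healthy donors, periodontitis
(PD), and periodontitis with type-2 diabetes (PDDM). The healthy group
is the reference in every methylation contrast; the two disease groups
are compared to each other for somatic burden. A direct PD-vs-PDDM
methylation contrast is available by passing `reference_group="PD"` to
`dm_test`, but the default follows the disease-vs-healthy reading of the
design.

## Statistical procedures

**Burden comparisons.** Two-group burden comparisons use the two-sided
Wilcoxon rank-sum test. When both samples are ≤ 25 and tie-free, the
exact null distribution is used (scipy); with ties and a pooled size
≤ 16, the exact p is obtained by full enumeration over group assignments
with mid-ranks, counting assignments whose statistic deviates from its
null mean at least as much as the observed one (the null is symmetric,
so this coincides with tail doubling in the tie-free case). Larger
samples use the normal approximation with tie correction and continuity
correction. A Welch t mode exists for compatibility with t-test figure
conventions.

**Substitution collapsing.** Single-base substitutions are collapsed
onto the pyrimidine strand: a purine reference is reverse-complemented
together with both flanking bases, mapping the 12 ordered base pairs 2:1
onto the six classes C>A, C>G, C>T, T>A, T>C, T>G. Spectra are counts
over the 96 COSMIC-ordered trinucleotide contexts; contexts come from an
indexed FASTA (pyfaidx) or a per-variant reference 3-mer column.
Signature matching is cosine similarity on raw counts (scale-invariant,
so equivalent to frequencies); only similarity *ranking* is computed —
exposure refitting (NNLS/NMF) is deliberately out of scope.

**Differential methylation.** Probes are filtered before testing:
detection p ≥ 0.01 in *any* sample removes the probe (the strictest
reading of the filter; a fraction-of-samples rule is available via
`detp_frac`), as does a bead count < 3 in ≥ 5 % of samples (boundary
inclusive). Each remaining probe gets a two-sided Welch t-test (unequal
variances, Welch–Satterthwaite df) of disease vs reference betas,
vectorised across probes; Benjamini–Hochberg adjustment runs across all
tested probes. A dmCpG call requires both q ≤ 0.05 and |Δβ| ≥ 0.2, with
Δβ = disease mean − reference mean; hyper and hypo are the two signs.
Degenerate probes (zero variance in both groups, equal means) are
assigned p = 1 and flagged. Normalisation (BMIQ/quantile) is assumed
done upstream; the package consumes normalised betas.

**Island relation.** CpG islands are 0-based half-open intervals;
positions inside an island are `Island`, within 2,000 bp of the nearest
edge `N_Shore`/`S_Shore` (N = lower coordinates), 2,001–4,000 bp
`N_Shelf`/`S_Shelf`, beyond `OpenSea`. Overlapping islands are a build
error.

**Gene-level integration.** Per-gene C>T counts (aggregated across a
group's patients) are joined to per-gene dmCpG counts; probes annotated
to several genes count for each. The Pearson correlation is computed on
genes with at least one C>T or one dmCpG in the chosen stratum — the
margins that actually appear on a burden-vs-methylation scatter — with
an `all_genes` option to keep zero rows; its p-value is the usual
t-transform on n−2 df. The hypo-vs-hyper excess test is a two-sided
Wilcoxon signed-rank on per-gene (hypo − hyper) counts restricted to
genes with ≥ 1 C>T, zeros dropped (Pratt mode optional); exact by
sign-pattern enumeration up to 16 non-zero differences, normal
approximation above. Correlations are computed on counts aggregated
across patients (one R per group), not per-patient. The promoter window
for joint hits is TSS1500, TSS200, 5'UTR, 1st exon.

**Interactions, pathways, enrichment.** Pairwise gene interactions use
the 2×2 patient table (both/only-A/only-B/neither), two-sided Fisher
exact p, and the sample odds ratio ad/bc with a Haldane 0.5 correction
applied to all cells when any cell is zero (so perfectly overlapping
genes get a large but finite OR); OR > 1 is labelled co-occurrence,
< 1 exclusivity; BH runs across pairs. Genes with fewer than
`min_carriers` (default 3) carriers, or mutated in every patient, are
excluded as uninformative. Pathway burden is the fraction of a group's
patients with ≥ 1 qualifying variant (any, or C>T-only) in any member
gene. "Mean hypo-methylation intensity" is operationalised as the
arithmetic mean hypo-dmCpG count per member gene (absent members count
as zero by default) — the quantity has no canonical definition in the
field and this choice is a documented best effort. Over-representation
is the upper-tail hypergeometric test of joint-hit genes against an
explicit universe (genes present in the integration table), BH across
sets.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes;
it is a stand-in with the right moments and coupling direction, not an
estimate of any real cohort.

- **Design & scale.** Defaults: 10 healthy / 15 PD / 11 PDDM patients;
  per-patient variant counts Poisson with means 0 / 564 / 589 (healthy
  donors contribute no somatic calls). Variants land in genes with
  probability ∝ gene length over a deterministic 120-gene panel
  (log-spaced lengths 5–200 kb, 2–4 promoter and 3–7 body probes per
  gene, 200 intergenic probes ⇒ 1,160 probes).
- **Substitutions.** 90 % SNP / 5 % INS / 5 % DEL. SNV contexts are
  drawn from the group's signature mixture over the bundled catalog
  (defaults: PD = 0.7·SBS6 + 0.3·SBS5, PDDM = 0.7·SBS1 + 0.3·SBS5);
  half the records are reported on the purine strand so the collapsing
  logic is genuinely exercised. The bundled catalog contains *synthetic*
  signature stand-ins echoing the qualitative shapes of SBS1 (C>T at
  NpCpG), SBS6 (C>T at non-CpG), SBS5 (flat with a T>C tilt) plus a
  uniform and a C>A-rich signature; they are not COSMIC profiles, and
  real analyses should load a published catalog file.
- **Methylation.** Probe baselines come from a bimodal beta mixture
  (unmethylated mode Beta(2,12), methylated mode Beta(12,2), 60 %
  methylated); per-sample betas are Beta(μν, (1−μ)ν) with dispersion
  ν = 100 (per-sample SD ≈ 0.035–0.05 at typical means). In a disease
  group, each probe of a gene with planted C>T count c is shifted down
  by `delta_beta_effect` (default 0.3) with probability
  1 − exp(−coupling·c/s), s = 3× the group's mean positive per-gene
  count; the saturating form keeps the probability responsive across a
  coupling grid and exactly zero at zero coupling. Downward-shifted
  probes start from the methylated range (baseline 0.65–0.9) so the
  effect is observable in [0, 1]. A small uncoupled hypermethylation
  background (2 % of gene probes, shifted up from a low baseline)
  reproduces the disease-wide hyper dmCpGs real cohorts show without
  tying them to mutations — this keeps the hyper stratum non-degenerate
  and makes the hypo-vs-hyper asymmetry testable.
- **Ground truth** records planted per-gene C>T counts, per-probe signed
  shifts, the coupling, the top-weight signature per group, and the
  planted promoter joint-hit genes.
- **What it does not emulate:** probe-type chemistry and normalisation
  artefacts, batch/slide effects, cell-type composition, linkage between
  neighbouring probes, germline contamination, and realistic gene-level
  mutation hotspots. Passing recovery tests therefore demonstrates the
  *analysis logic* is correct under the assumed structure, not that the
  pipeline is robust to those real-data complications.

## Numerical and testing choices

- Exact-test enumeration limits: pooled n ≤ 16 (rank-sum with ties),
  n ≤ 16 non-zero differences (signed-rank), n ≤ 25 tie-free (scipy
  exact). Beyond these, normal approximations with tie correction.
- Percent rounding is half-away-from-zero (so 6/11 → 55 %).
- Multi-seed simulation tests run on a reduced cohort (40 genes, 6/8/7
  patients, rates 80/90, ≈ 340 probes) chosen so 50-seed loops stay
  inexpensive while keeping every distributional mechanism identical;
  scale-sensitive checks (the 564/589 burden means, group signature
  identities) run on the full default cohort.
- Pipeline runs are deterministic given config and inputs; the report
  JSON validates against `schemas/run_report.schema.json`, and stage
  failures are recorded with dependents skipping explicitly.

## Known limitations

- The emulated pathway C>T burden saturates near 100 % because several
  hundred variants per patient are spread over only 120 genes; the
  real-cohort percentages (tens of percent) arise from a ~20,000-gene
  exome, which the desk-scale panel does not represent.
- Signature cosines against the synthetic catalog are higher than
  published values against full COSMIC catalogs (which contain many
  correlated signatures); only the top-1 identity is meaningful here.
- The correlation between C>T burden and hypo dmCpG count in the default
  cohort (R ≈ 0.8) reflects the chosen coupling strength, which the
  underlying study does not parameterise; treat it as a demonstration of
  recoverability, not an estimate.
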
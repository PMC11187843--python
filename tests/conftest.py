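import numpy as np
import pandas as pd
import pytest

from somameth.synthetic import CohortSpec, GeneModel, generate_cohort, write_fixture_bundle


def small_spec(seed: int = 7, **overrides) -> CohortSpec:
    """Reduced cohort for fast simulation loops: fewer genes, lower rates."""
    defaults = dict(
        n_per_group={"healthy": 6, "PD": 8, "PDDM": 7},
        gene_models=[
            GeneModel(f"G{i + 1:03d}", 5_000 + 4_000 * i, 2 + i % 2, 3 + i % 3)
            for i in range(40)
        ],
        mutation_rate={"healthy": 0.0, "PD": 80.0, "PDDM": 90.0},
        n_igr_probes=40,
        seed=seed,
    )
    defaults.update(overrides)
    return CohortSpec(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_spec())


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size cohort at the study's group sizes and burden scale."""
    return generate_cohort(CohortSpec(seed=11))


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory):
    d = tmp_path_factory.mktemp("bundle")
    manifest = write_fixture_bundle(small_spec(seed=5), d)
    return d, manifest


@pytest.fixture()
def toy_maf(tmp_path):
    """Three-row MAF using standard column aliases: one SNP, one INS, one DEL."""
    path = tmp_path / "toy.maf"
    path.write_text(
        "Hugo_Symbol\tTumor_Sample_Barcode\tgroup\tChromosome\tStart_Position\t"
        "Reference_Allele\tTumor_Seq_Allele2\n"
        "TP53\tPD01\tPD\tchr17\t7578406\tC\tT\n"
        "NEB\tPD01\tPD\tchr2\t152432000\t-\tAG\n"
        "OBSCN\tPD02\tPD\tchr1\t228400000\tGT\t-\n"
    )
    return path
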
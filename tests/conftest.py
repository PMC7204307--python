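import numpy as np
import pandas as pd
import pytest

from cinscore import CIN70, SimulationConfig, generate_cohort
from cinscore.genome import GenomeArmModel
from cinscore.simulate import generate_arm_model


@pytest.fixture(scope="session")
def toy_model() -> GenomeArmModel:
    """2 chromosomes / 4 arms of 1 Mb each with a 40-gene catalog."""
    cfg = SimulationConfig(arms=4, arm_length_bp=1_000_000, n_genes=40,
                           n_signature_genes=5, seed=11)
    return generate_arm_model(cfg)


@pytest.fixture(scope="session")
def bimodal_cohort():
    """Default-structure cohort scaled down: five stage classes, bimodal M1."""
    cfg = SimulationConfig(
        n_samples_per_group={"M0-NM": 10, "M0-oligo": 4, "M0-poly": 4,
                             "M1-oligo": 10, "M1-poly": 12},
        n_genes=600,
        n_signature_genes=70,
        signature_gene_symbols=CIN70.genes,
        seed=21,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def strong_cohort():
    """Strongly separated two-group cohort: planted 2-fold signature genes
    (latent CIN 0 vs 1, unimodal, cin_effect 1 log2/unit)."""
    cfg = SimulationConfig(
        n_samples_per_group={"M0-NM": 20, "M1-poly": 20},
        group_cin_means={"M0-NM": 0.0, "M1-poly": 1.0},
        m1_bimodal_weight=0.0,
        cin_sd=0.05,
        n_genes=800,
        n_signature_genes=50,
        signature_gene_symbols=CIN70.genes[:50],
        seed=33,
    )
    return generate_cohort(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2026)


@pytest.fixture(scope="session")
def null_matrix() -> pd.DataFrame:
    """Gaussian log-scale matrix with no group structure."""
    r = np.random.default_rng(7)
    return pd.DataFrame(
        r.normal(6.0, 1.0, size=(120, 16)),
        index=[f"g{i:03d}" for i in range(120)],
        columns=[f"s{j:02d}" for j in range(16)],
    )
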
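import numpy as np
import pandas as pd
import pytest

from triopgs.sumstats_io import GenotypePanel, SummaryStats
from triopgs.synthetic_data import OutcomeModel, SimulationConfig, simulate_study


@pytest.fixture
def tiny_panel() -> GenotypePanel:
    """One complete trio, five variants, hand-set dosages (alt-allele copies)."""
    samples = pd.DataFrame(
        {
            "family_id": ["F1"] * 3,
            "sample_id": ["F1-FA", "F1-MO", "F1-PR"],
            "father_id": ["", "", "F1-FA"],
            "mother_id": ["", "", "F1-MO"],
            "sex": ["1", "2", "1"],
            "role": ["father", "mother", "proband"],
            "batch": ["batch1"] * 3,
        }
    )
    variants = pd.DataFrame(
        {
            "variant_id": [f"rs{i}" for i in range(1, 6)],
            "chrom": ["1"] * 5,
            "pos": [100, 200, 300, 400, 500],
            "ref": ["G", "G", "A", "T", "A"],
            "alt": ["A", "A", "T", "C", "G"],
        }
    )
    dosages = np.array(
        [
            [0, 1, 2, 1, 0],
            [1, 1, 0, 2, 1],
            [1, 2, 1, 2, 0],
        ],
        dtype=float,
    )
    return GenotypePanel.from_parts(samples, variants, dosages)


@pytest.fixture
def tiny_sumstats() -> SummaryStats:
    """Weights matched to tiny_panel: rows 1-2 aligned, row 3 swapped, 4-5 direct."""
    df = pd.DataFrame(
        {
            "variant_id": [f"rs{i}" for i in range(1, 6)],
            "chrom": ["1"] * 5,
            "pos": [100, 200, 300, 400, 500],
            "effect_allele": ["A", "A", "C", "C", "G"],
            "other_allele": ["G", "G", "T", "T", "A"],
            "weight": [0.2, -0.1, 0.3, 0.05, -0.25],
            "pvalue": [0.0005, 0.004, 0.03, 0.3, 0.9],
            "eaf": [0.3, 0.4, 0.5, 0.2, 0.1],
        }
    )
    return SummaryStats.from_frame(df)


@pytest.fixture(scope="session")
def small_study():
    """A 60-trio cohort with a strong, noise-free all-causal architecture."""
    cfg = SimulationConfig(
        n_trios=60,
        n_variants=300,
        n_causal=300,
        h2_pgs=0.3,
        ascertainment_quantile=0.2,
        discovery_n=np.inf,
        missing_rate=0.02,
        seed=11,
        outcome_models=(
            OutcomeModel("insomnia", -1.07, np.log(1.5)),
            OutcomeModel("hypersomnia", -3.15, 0.0),
        ),
    )
    return simulate_study(cfg)
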
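import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from dosetrend import AcuteDesign, ExpressionMatrix, QpcrPlate, generate_acute_experiment

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def tiny_matrix():
    """4 genes x 4 samples with a hand-checkable design."""
    values = pd.DataFrame(
        {
            "s1": [1.0, 3.0, 5.0, 7.0],
            "s2": [2.0, 4.0, 6.0, 8.0],
            "s3": [1.5, 3.5, 5.5, 7.5],
            "s4": [2.5, 4.5, 6.5, 8.5],
        },
        index=["g1", "g2", "g3", "g4"],
    )
    design = pd.DataFrame(
        {
            "drug": "bleomycin",
            "dose_score": [1, 2, 3, 1],
            "time_h": [6, 6, 6, 24],
            "replicate": [1, 1, 1, 1],
        },
        index=values.columns,
    )
    return ExpressionMatrix(values=values, design=design, level="gene")


@pytest.fixture(scope="session")
def spiked_acute():
    """The spiked regression design: 500 genes, 25 trend genes, effect 1.0."""
    design = AcuteDesign(
        n_genes=500, n_trend_genes=25, effect_size_log2=1.0, noise_sd_log2=0.5,
        replicates_per_group=2, seed=7,
    )
    return generate_acute_experiment(design)


@pytest.fixture
def triplicate_plate():
    rows = []
    for gene, cts in {
        "GDF15": {(u, t): ct for (u, t), ct in {
            ("control", 6): 30.0, ("control", 24): 30.0, ("control", 48): 30.0,
            ("treated", 6): 30.0, ("treated", 24): 27.0, ("treated", 48): 24.0,
        }.items()},
        "GAPDH": {(u, t): 20.0 for u in ("control", "treated") for t in (6, 24, 48)},
    }.items():
        for (cond, t), ct in cts.items():
            for rep in (1, 2, 3):
                rows.append({"gene": gene, "condition": cond, "time_h": t,
                             "replicate": rep, "ct": ct})
    return QpcrPlate(wells=pd.DataFrame(rows))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
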
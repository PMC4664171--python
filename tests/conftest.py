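import numpy as np
import pandas as pd
import pytest

from oameqtl.discovery import CohortData
from oameqtl.simulate import LocusSim, SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_config():
    """A light-weight study: 3 loci, few probes, one planted effect."""
    return SimConfig(
        n_oa_knee=30,
        n_oa_hip=10,
        n_nof=10,
        loci=(
            LocusSim("locusA", 0.35, 20, True, planted={10: -0.5}),
            LocusSim("locusB", 0.25, 15),
            LocusSim("locusC", 0.40, 10, False, planted={5: -0.4}),
        ),
        n_replication_oa=24,
        n_replication_nof=4,
        n_expression=12,
    )


def make_cohort(n=30, n_probes=5, seed=0, maf=0.4):
    """Hand-assembled cohort with independent uniform betas (null data)."""
    rng = np.random.default_rng(seed)
    ids = [f"S{i:03d}" for i in range(n)]
    samples = pd.DataFrame(
        {
            "status": ["OA"] * (n - n // 4) + ["NOF"] * (n // 4),
            "joint": ["knee"] * (n // 2)
            + ["hip"] * (n - n // 4 - n // 2)
            + ["none"] * (n // 4),
            "sex": list(np.where(rng.random(n) < 0.5, "male", "female")),
        },
        index=pd.Index(ids, name="sample_id"),
    )
    dosages = pd.DataFrame(
        {"rsTEST": rng.binomial(2, maf, n)}, index=samples.index,
        dtype=float,
    )
    betas = pd.DataFrame(
        rng.uniform(0.1, 0.9, (n, n_probes)),
        index=samples.index,
        columns=[f"cg{i:05d}" for i in range(n_probes)],
    )
    return CohortData(samples=samples, dosages=dosages, betas=betas)
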
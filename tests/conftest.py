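"""Shared fixtures: the canonical synthetic study and derived results.

Heavy objects (the default 2000-gene three-region study, its DE contrast
table and consensus network) are session-scoped so the recovery tests share
one computation.
"""

import numpy as np
import pandas as pd
import pytest

from tetranet.consensus_network import build_consensus_network
from tetranet.data_model import DIAGNOSES, MANNER_LEVELS, REGIONS, SampleTable
from tetranet.differential_expression import run_differential_expression
from tetranet.synthetic_data import SimulationConfig, simulate_study

CANONICAL_SEED = 1


@pytest.fixture(scope="session")
def default_study():
    """The canonical planted-structure fixture: 19 tetrads, 2000 genes,
    3 regions, 5 planted modules, graded DE burden."""
    return simulate_study(SimulationConfig(seed=CANONICAL_SEED))


@pytest.fixture(scope="session")
def default_contrasts(default_study):
    studies, _ = default_study
    return run_differential_expression(studies)


@pytest.fixture(scope="session")
def default_network(default_study):
    studies, _ = default_study
    return build_consensus_network(studies, seed=CANONICAL_SEED)


def make_sample_table(n_tetrads=2, regions=("HIP",), diagnoses=DIAGNOSES,
                      seed=0) -> SampleTable:
    """Small, valid tetrad-design metadata for unit tests."""
    rng = np.random.default_rng(seed)
    rows = []
    for t in range(1, n_tetrads + 1):
        sex = "F" if t % 2 else "M"
        for dx in diagnoses:
            subj = f"S{t}{dx}"
            age = 40 + 5 * t + rng.normal(0, 1)
            pmi = float(rng.uniform(5, 20))
            ph = float(rng.uniform(6.4, 7.2))
            tob = "yes" if rng.random() < 0.5 else "no"
            manner = MANNER_LEVELS[rng.integers(3)]
            for region in regions:
                rows.append({
                    "sample_id": f"{subj}.{region}", "subject_id": subj,
                    "tetrad_id": t, "region": region, "diagnosis": dx,
                    "age": age, "sex": sex, "tobacco": tob,
                    "manner_of_death": manner, "pmi": pmi, "ph": ph,
                })
    return SampleTable(pd.DataFrame(rows))
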
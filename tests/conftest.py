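import numpy as np
import pandas as pd
import pytest

from mpalkit.io import BetaMatrix
from mpalkit.simulate import SimulationDesign, simulate_cohort


@pytest.fixture(scope="session")
def small_design() -> SimulationDesign:
    """Compact cohort: 30 tumors, 1600 probes over 8 chromosomes, 400 genes."""
    return SimulationDesign(
        n_myeloid_B=14, n_myeloid_T=16,
        n_ref_AML=15, n_ref_BALL=15, n_ref_TALL=15,
        n_probes=1600, n_lineage_probes=120, n_signature_probes=90,
        n_genes=400, n_de_genes=24, seed=5,
    )


@pytest.fixture(scope="session")
def cohort_dir(small_design, tmp_path_factory):
    out = tmp_path_factory.mktemp("cohort")
    simulate_cohort(small_design, out)
    return out


@pytest.fixture(scope="session")
def cohort_truth(cohort_dir):
    import json

    with open(cohort_dir / "truth.json") as fh:
        return json.load(fh)


def make_beta(values: np.ndarray, probe_prefix="cg", sample_prefix="S") -> BetaMatrix:
    n, m = values.shape
    return BetaMatrix(
        pd.DataFrame(
            values,
            index=pd.Index([f"{probe_prefix}{i:05d}" for i in range(n)], name="probe_id"),
            columns=[f"{sample_prefix}{j:02d}" for j in range(m)],
        )
    )
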
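import numpy as np
import pytest

from pedimpute.pipeline import run_masking_experiment
from pedimpute.simulator import SimConfig, simulate_dataset

# a small family echoing the worked example in the method description:
# 652 x 653 -> 651; 583 x 584 -> 619, 628; 619 x 651 -> 650; 628 x 627 -> 629
FIG1_PED = """\
10 652 0 0 1 0
10 653 0 0 2 0
10 651 652 653 2 0
10 583 0 0 1 0
10 584 0 0 2 0
10 619 583 584 1 0
10 628 583 584 2 0
10 650 619 651 1 0
10 627 0 0 1 0
10 629 627 628 2 0
"""


@pytest.fixture
def fig1_path(tmp_path):
    p = tmp_path / "fig1.ped"
    p.write_text(FIG1_PED)
    return p


@pytest.fixture(scope="session")
def dense_cfg():
    return SimConfig(n_set1=2000, n_set2=5000)


@pytest.fixture(scope="session")
def dense_sim(dense_cfg):
    """Error-free gene-drop on the demo pedigree at high framework density."""
    return simulate_dataset(cfg=dense_cfg, seed=1)


@pytest.fixture(scope="session")
def dense_masked(dense_sim):
    """50% uniform masking experiment on the dense simulation."""
    imp, report, record, result = run_masking_experiment(
        dense_sim, scheme="uniform_rate", rate=0.5, seed=101
    )
    return {"imp": imp, "report": report, "record": record, "result": result}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
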
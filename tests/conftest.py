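import numpy as np
import pytest

from promreg.io_formats import GenomicInterval, TFBRSet, TSSRecord
from promreg.synthetic_data import SimConfig, simulate_dataset


def make_tss(tss_id="t1", chrom="chr1", position=10_000, strand="+", el=None):
    return TSSRecord(tss_id=tss_id, chrom=chrom, position=position,
                     strand=strand, el=el or {})


def make_set(tf, intervals, caller="final", experiment_id="e1", cell_line="CL"):
    return TFBRSet(
        tf=tf, cell_line=cell_line, experiment_id=experiment_id, caller=caller,
        intervals=[GenomicInterval(*iv) for iv in intervals],
    )


@pytest.fixture(scope="session")
def small_dataset():
    """A small seeded end-to-end simulation shared across read-only tests."""
    effects = {
        "TF000[1, 100]": 0.4,
        "TF002[-100, 0]": -0.3,
        "TF004[501, 1000]": 0.25,
    }
    cfg = SimConfig(seed=7, n_tss=1500, m_tfs=8, close_pair_fraction=0.0,
                    binding_propensity=0.3, true_effects=effects)
    return simulate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
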
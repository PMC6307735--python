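import numpy as np
import pytest

from isoflux.core import D2O_WEIGHT_MG, EMPTY_ROTOR_MG, SampleRecord
from isoflux.roi_template import default_template
from isoflux.synthetic_data import EffectSpec, assign_true_state


def make_sample(tissue="brain_cortex", group="ACE", horn="AGA",
                fetus_id="T-M1-AGA-F1", net=50.0) -> SampleRecord:
    return SampleRecord(
        fetus_id=fetus_id, mother_id="T-M1", horn=horn, group=group,
        tissue=tissue,
        rotor_total_weight_mg=EMPTY_ROTOR_MG + D2O_WEIGHT_MG + net,
        net_tissue_weight_mg=net, birthweight_g=50.0, placental_weight_g=5.5)


@pytest.fixture(scope="session")
def template():
    return default_template()


@pytest.fixture(scope="session")
def ace_brain_sample():
    return make_sample("brain_cortex", "ACE")


@pytest.fixture(scope="session")
def ace_brain_state(ace_brain_sample):
    """Deterministic (cv=0) acetate-infusion brain ground truth."""
    return assign_true_state(ace_brain_sample, None, EffectSpec(),
                             master_seed=11, cv=0.0, drift=False)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
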
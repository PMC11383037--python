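import warnings

import numpy as np
import pytest

from caspevo.core import SpeciesTree

warnings.filterwarnings("ignore", category=DeprecationWarning)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(42)


def balanced12_tree(b: float = 0.35) -> SpeciesTree:
    nwk = (
        f"(((A:{b},B:{b}):{b},(C:{b},D:{b}):{b}):{b},"
        f"((E:{b},F:{b}):{b},(G:{b},H:{b}):{b}):{b},"
        f"((I:{b},J:{b}):{b},(K:{b},L:{b}):{b}):{b});"
    )
    return SpeciesTree.from_newick(nwk)


@pytest.fixture(scope="session")
def calibration_tree():
    return balanced12_tree()


@pytest.fixture(scope="session")
def primate_dataset():
    """Event-rich simulated dataset shared across tests (seed fixed)."""
    from caspevo.sim import primate_like, simulate_dataset

    cfg = primate_like(seed=1, scale=0.25)
    loci, truth = simulate_dataset(cfg)
    return cfg, loci, truth


@pytest.fixture(scope="session")
def rodent_dataset():
    from caspevo.sim import rodent_like, simulate_dataset

    cfg = rodent_like(seed=2, scale=0.25)
    loci, truth = simulate_dataset(cfg)
    return cfg, loci, truth


@pytest.fixture(scope="session")
def primate_calls(primate_dataset):
    from caspevo.pipeline import annotate_and_classify
    from caspevo.sim import reference_set_from_truth

    _, loci, truth = primate_dataset
    reference = reference_set_from_truth(truth, "Macaque")
    return {sp: annotate_and_classify(loci[sp], reference) for sp in loci}, reference


@pytest.fixture(scope="session")
def rodent_calls(rodent_dataset):
    from caspevo.pipeline import annotate_and_classify
    from caspevo.sim import reference_set_from_truth

    _, loci, truth = rodent_dataset
    reference = reference_set_from_truth(truth, "Rat")
    return {sp: annotate_and_classify(loci[sp], reference) for sp in loci}, reference
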
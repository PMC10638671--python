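import numpy as np
import pandas as pd
import pytest

import cistrans_atac as ct


@pytest.fixture(scope="session")
def mixed_run():
    """A mixed six-mode simulation classified end to end (shared, read-only)."""
    truth = ct.make_truth(
        600,
        {m: 1 / 6 for m in ct.REGULATORY_MODES},
        effect_size_law=1.5,
        seed=11,
        baseline_mean=300.0,
        dispersion=0.05,
    )
    cm, descriptors = ct.simulate_counts(truth, ct.SimulationDesign(seed=12))
    cm = ct.size_factors(ct.cpm_filter(cm, descriptors), descriptors)
    calls = ct.classify_all(cm, descriptors)
    return {"truth": truth, "cm": cm, "descriptors": descriptors, "calls": calls}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
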
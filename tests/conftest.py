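import numpy as np
import pytest

from uroscent import SimulationDesign, simulate_chromatograms, simulate_voc_table


@pytest.fixture(scope="session")
def small_voc_table():
    """36-sample study-sized table with seven planted compounds."""
    design = SimulationDesign(n_case=6, n_control=30, seed=11)
    return simulate_voc_table(design)


@pytest.fixture(scope="session")
def planted_chromatograms():
    """100 chromatograms with the default planted peak layout."""
    design = SimulationDesign(n_case=50, n_control=50, seed=7)
    chroms, records = simulate_chromatograms(design)
    labels = np.array([r.cohort for r in records], dtype=object)
    return chroms, labels
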
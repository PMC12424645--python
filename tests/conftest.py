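import numpy as np
import pytest

import abepitope as ab


@pytest.fixture
def ab140() -> ab.ModifiedPeptide:
    return ab.ModifiedPeptide(ab.AB40_SEQUENCE, abeta_start=1)


@pytest.fixture
def default_scan() -> ab.ProbeLibrary:
    return ab.positional_scan("DAEFRHDSGYEVHHQKLV", abeta_start=1)


@pytest.fixture
def kinetic_params() -> ab.KineticParams:
    return ab.KineticParams(kon=2e5, koff=2.8e-4, rmax=1.0)


@pytest.fixture
def noiseless_dms():
    """Noiseless synthetic scan: planted core recoverable exactly."""
    truth = ab.DmsTruth(noise_sigma=0.0)
    table, library, record = ab.simulate_dms_array(truth, replicates=1, seed=0)
    return truth, table, library, record


def brute_force_core_positions(ratios: dict, min_count: int = 10, threshold: float = 0.5):
    """Independent reference implementation of the core-motif counting rule.

    ``ratios`` maps position -> {letter: ratio}.  A position is core when at
    least ``min_count`` of its substitutions fall strictly below the ratio
    threshold.
    """
    core = []
    for pos in sorted(ratios):
        n = 0
        for letter in ratios[pos]:
            if ratios[pos][letter] < threshold:
                n += 1
        if n >= min_count:
            core.append(pos)
    return core
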
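import numpy as np
import pytest

import timmrd as T


@pytest.fixture(scope="session")
def small_spec():
    return T.SimulationSpec(n_blocks=40, n_dmb_true=40, seed=42, depth_mean=200.0)


@pytest.fixture(scope="session")
def small_world(small_spec):
    """Prior, tissue pair, and all-DMB panel on a 40-block synthetic panel."""
    prior = T.true_background_prior(small_spec)
    tumor, normal, planted = T.simulate_tissue_pair(small_spec, prior)
    panel = T.PatientPanel(
        "P1",
        [T.PanelBlock(b, tumor.level(b), normal.level(b)) for b in sorted(planted)],
    )
    return {"spec": small_spec, "prior": prior, "tumor": tumor,
            "normal": normal, "panel": panel}


@pytest.fixture(scope="session")
def surveil_result():
    """One 200-patient end-to-end surveillance run shared across tests."""
    from timmrd.studies import surveillance_study

    return surveillance_study(20260928 % (2**31), n_patients=200)


def make_counts(pairs, sample_id="s"):
    counts = T.BlockCounts(sample_id)
    for block_id, (n, m) in pairs.items():
        counts.add(block_id, n, m)
    return counts
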
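import numpy as np
import pytest

from ap2kit import synthetic_data as sd


@pytest.fixture(scope="session")
def profiles():
    """Calibrated AP2 + B3 profiles from the synthetic seed alignments."""
    return sd.default_profiles(n_shuffles=500)


@pytest.fixture(scope="session")
def small_sim_params():
    return sd.SimParams(
        rng_seed=42, n_decoys=60, n_ap2_members=6, n_rav_members=4,
        n_single_members=24, tandem_clusters=((3, 0.85), (2, 0.80)),
        segmental_identities=(0.80,), n_de_effects=10,
    )


@pytest.fixture(scope="session")
def small_genome(small_sim_params, profiles):
    """A compact synthetic genome bundle shared across unit tests."""
    records, models, truth = sd.gen_proteome_gff(small_sim_params, profiles)
    anchors, queries = sd.gen_reference_sets(small_sim_params, profiles)
    blocks = sd.gen_synteny_blocks(small_sim_params, truth, models)
    return {"records": records, "models": models, "truth": truth,
            "anchors": anchors, "queries": queries, "blocks": blocks,
            "params": small_sim_params}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
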
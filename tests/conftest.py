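import numpy as np
import pytest

import chromoseed as cs


@pytest.fixture(scope="session")
def sphere_params():
    """Fixture-scale confinement: 200 nm sphere, default bead geometry."""
    return cs.PhysicalParams(confinement_radius_nm=200.0)


@pytest.fixture(scope="session")
def s2r_region_params():
    """S2R+ physical parameters for a 0.2 Mb region (100 beads at 2 kb)."""
    return cs.params_for_cell("s2r+", region_length_mb=0.2)


@pytest.fixture(scope="session")
def null100(s2r_region_params):
    """Null ensemble for the 100-bead study region (10^4 chains)."""
    cfg = cs.GrowthConfig(n_beads=100, n_chains=10_000, master_seed=11)
    return cs.build_null_ensemble(cfg, s2r_region_params)


@pytest.fixture(scope="session")
def null100_map(null100):
    return cs.contact_probability(null100).p_null


@pytest.fixture(scope="session")
def null_decay_profile(null100_map):
    """Per-separation stratum means of the null map, used as a physically
    realizable baseline for synthetic Hi-C."""
    pn = null100_map
    n = pn.shape[0]
    prof = np.empty(n)
    prof[0] = 1.0
    for s in range(1, n):
        prof[s] = np.mean([pn[i, i + s] for i in range(n - s)])
    return prof


@pytest.fixture(scope="session")
def recovery_toy(null_decay_profile):
    """Canonical recovery fixture: 3 TADs + 3 loops on the null baseline."""
    spec = cs.ToySpec(
        n_bins=100,
        tads=[(5, 35, 3.0), (35, 65, 3.0), (65, 95, 3.0)],
        loops=[(10, 60, 8.0), (20, 80, 8.0), (40, 90, 8.0)],
        noise_dispersion=0.1,
        seed=1,
        decay_profile=null_decay_profile,
    )
    matrix, labels = cs.generate_toy_hic(spec)
    return spec, matrix, labels


@pytest.fixture(scope="session")
def recovery_calls(recovery_toy, null100):
    """Specific-interaction calls on the canonical recovery fixture."""
    _, matrix, _ = recovery_toy
    pmap = cs.compute_propensity(cs.ice_balance(matrix))
    calls = cs.call_specific_interactions(
        pmap, null100, cs.BootstrapConfig(n_replicates=2000, seed=3))
    return pmap, calls
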
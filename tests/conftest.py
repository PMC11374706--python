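"""Shared fixtures: small synthetic ensembles reused across the suite.

Expensive Monte Carlo ensembles are session-scoped so each is generated
once per run.
"""

import numpy as np
import pytest

from prefold import PREParameters
from prefold.chains import ChainModelParams, sample_coil_ensemble

# 38-residue mixed-composition test sequence (two labelling positions have
# ordinary sidechain-bearing residues; sites only need backbone + CB)
SMALL_SEQ = "AKTVEGSLDAFKTVNGELSTAKDVFGSLTNAEKGVDSL"


@pytest.fixture(scope="session")
def small_coil():
    """50-conformer free coil of the 38-residue test sequence."""
    params = ChainModelParams(sequence=SMALL_SEQ, n_conformers=50, seed=3,
                              burn_in_sweeps=60, stride_sweeps=3)
    return sample_coil_ensemble(params)


@pytest.fixture(scope="session")
def small_tethered():
    """30-conformer tethered coil (C terminus pinned, wall at z = -3 Å)."""
    params = ChainModelParams(sequence=SMALL_SEQ, n_conformers=30, seed=7,
                              tether=("C", -3.0), burn_in_sweeps=60,
                              stride_sweeps=3)
    return sample_coil_ensemble(params)


@pytest.fixture(scope="session")
def pre_params():
    return PREParameters(tau_c=3e-9)


@pytest.fixture(scope="session")
def truth_weights():
    """Fixed non-uniform Dirichlet truth weights for recovery tests."""
    return np.random.default_rng(0).dirichlet(np.ones(50))


@pytest.fixture(scope="session")
def noise_free_pre(small_coil, pre_params, truth_weights):
    """Noise-free restraints generated from known truth weights at two
    labelling sites, plus the cached forward model."""
    from prefold import synth_pre_dataset
    truth = small_coil.with_weights(truth_weights)
    restraints, model = synth_pre_dataset(truth, [10, 30], pre_params,
                                          noise_sd=0.0, seed=1)
    return restraints, model


@pytest.fixture(scope="session")
def iso_study():
    """Reduced-size isolated-like study ensemble (114 residues, 28 frames)."""
    from prefold.chains import isolated_like_ensemble
    return isolated_like_ensemble(n_conformers=28, seed=11)


@pytest.fixture(scope="session")
def rnc_study():
    """Reduced-size tethered-like study ensemble (114 residues, 28 frames)."""
    from prefold.chains import tethered_like_ensemble
    return tethered_like_ensemble(n_conformers=28, seed=12)


@pytest.fixture(scope="session")
def compact_study():
    """Strongly compacted 114-residue ensemble (R_g target 22 Å).

    Backbone-only chains bury measurable surface only well below the
    study's isolated-state compactness, so surface-burial sign checks use
    this deeper compaction."""
    params = ChainModelParams(n_conformers=15, seed=21,
                              compaction_bias=(22.0, 0.5),
                              first_residue_id=637)
    return sample_coil_ensemble(params)
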
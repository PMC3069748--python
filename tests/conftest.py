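"""Shared fixtures: small fast crystals for unit tests, and a session-scoped
batch of reference toy-problem simulations reused across the acceptance
tests (simulation, error-model refinement and posteriors are the expensive
parts, so they are computed once per seed)."""

import numpy as np
import pytest

from friedel import (
    ExperimentSpec,
    SpaceGroup,
    UnitCell,
    flag_free_set,
    generate_structure,
    simulate_dataset,
    simulate_toy50,
)
from friedel.phasing import phase_posteriors, refine_error_model


SMALL_CELL = UnitCell(20.0, 24.0, 22.0, 90.0, 90.0, 90.0)


def make_small_crystal(seed=0, sg="P21", n_light=40, n_heavy=2, d_min=2.5,
                       noise_frac=0.05, f_dprime=4.0):
    """A light-weight P21 (or P1) crystal for unit tests (~1200 reflections)."""
    structure = generate_structure(
        seed, SMALL_CELL, SpaceGroup(sg), n_light,
        [("Se", n_heavy, -2.0, f_dprime)],
    )
    datasets, truth = simulate_dataset(
        structure,
        ExperimentSpec(kind="SAD", channels=[("peak", -2.0, f_dprime)],
                       d_min=d_min, noise_frac=noise_frac, seed=seed + 7),
    )
    return structure, datasets[0], truth


@pytest.fixture(scope="session")
def small_crystal():
    return make_small_crystal(0)


@pytest.fixture(scope="session")
def small_crystal_noise_free():
    return make_small_crystal(0, noise_frac=0.0)


@pytest.fixture(scope="session")
def toy50_case():
    """One reference toy-problem dataset with free set, error model and
    joint posteriors (true substructure)."""
    st, data, truth = simulate_toy50(0)
    data = flag_free_set(data, 0.05, seed=101)
    em = refine_error_model(data, st.heavy, max_iter=12, max_refl_per_shell=80)
    phases = phase_posteriors(data, st.heavy, em)
    return st, data, truth, em, phases


N_BATCH = 20


@pytest.fixture(scope="session")
def toy50_batch():
    """Reference toy-problem simulations for seeds 0..N_BATCH-1.

    Each record: (structure, data-with-free-set, truth, error model,
    joint posteriors, merged-difference Gaussian posteriors).
    """
    out = []
    for seed in range(N_BATCH):
        st, data, truth = simulate_toy50(seed)
        data = flag_free_set(data, 0.05, seed=101 + seed)
        em = refine_error_model(data, st.heavy, max_iter=12, max_refl_per_shell=80)
        ph_joint = phase_posteriors(data, st.heavy, em)
        ph_gauss = phase_posteriors(data, st.heavy, em, mode="gaussian_df")
        out.append((st, data, truth, em, ph_joint, ph_gauss))
    return out
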
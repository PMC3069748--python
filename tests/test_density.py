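"""Map synthesis, solvent flattening, phase combination, hand determination."""

import numpy as np
import pytest

from friedel import ReflectionSet, Site, SpaceGroup, Substructure, UnitCell
from friedel.density import (
    combine_phases_mlhl,
    combine_phases_multivariate,
    determine_hand,
    estimate_comb_errors_cv,
    map_to_sf,
    modify_density,
    run_dm_cycles,
    solvent_mask,
    synthesize_map,
)
from friedel.maps import MapGrid, suggest_grid_dims
from friedel.reflections import PhaseDistribution
from friedel.phasing import phase_quality_vs_truth


@pytest.fixture(scope="module")
def dm_setup(toy50_case):
    st, data, truth, em, phases = toy50_case
    dims = suggest_grid_dims(data.cell, data.sg, data.d_min)
    grid = synthesize_map(data, phases, dims, fom_weights=phases.fom * (~data.free))
    mask = solvent_mask(grid, 0.45, data.d_min, sg=data.sg)
    dm = map_to_sf(modify_density(grid, mask), data)
    em_cv = estimate_comb_errors_cv(data, phases, dm, em)
    return st, data, truth, em, phases, grid, mask, dm, em_cv


def test_single_reflection_synthesis_is_cosine_wave():
    cell = UnitCell(10, 10, 10)
    sg = SpaceGroup("P1")
    data = ReflectionSet(cell=cell, sg=sg, hkl=np.array([[2, 0, 0]]),
                         f_plus=np.array([5.0]), sig_plus=np.array([0.1]),
                         f_minus=np.array([5.0]), sig_minus=np.array([0.1]),
                         d_min=5.0, d_max=5.0)
    ph = PhaseDistribution(data.hkl, np.zeros((1, 4)), np.array([0.0]), np.array([1.0]))
    grid = synthesize_map(data, ph, (12, 12, 12))
    x = np.arange(12) / 12.0
    expected = 2 * 5.0 * np.cos(2 * np.pi * 2 * x) / cell.volume
    assert np.allclose(grid.values[:, 0, 0], expected, atol=1e-10)


def test_zero_fom_gives_flat_map(dm_setup):
    _, data, _, _, phases, *_ = dm_setup
    grid = synthesize_map(data, phases, fom_weights=np.zeros(data.n))
    assert np.allclose(grid.values, 0.0)


def test_below_nyquist_grid_rejected(dm_setup):
    _, data, _, _, phases, *_ = dm_setup
    with pytest.raises(ValueError, match="Nyquist"):
        synthesize_map(data, phases, (8, 8, 8))


def test_synthesis_transform_round_trip(dm_setup):
    _, data, _, _, phases, *_ = dm_setup
    grid = synthesize_map(data, phases)
    back = map_to_sf(grid, data)
    coeff = phases.fom * data.f_mean
    strong = coeff > 1.0
    rel = np.abs(back.f_dm[strong] - coeff[strong]) / coeff[strong]
    dphi = np.abs((back.phi_dm - phases.phi_best + 180.0) % 360.0 - 180.0)
    assert rel.max() < 1e-6
    assert dphi[strong].max() < 1e-6


def test_map_against_direct_summation_oracle(toy50_case):
    """True phases + amplitudes: the FFT synthesis correlates with a
    direct-summation density evaluated on a coarse grid."""
    st, data, truth, _, _ = toy50_case
    ph = PhaseDistribution(truth.hkl, np.zeros((len(truth.hkl), 4)),
                           truth.phi_p, np.ones(len(truth.hkl)), truth.centric)
    dtrue = data.copy()
    dtrue.f_plus = truth.f_plus_true["peak"].copy()
    dtrue.f_minus = truth.f_minus_true["peak"].copy()
    dtrue.sig_plus = np.ones(data.n)
    dtrue.sig_minus = np.ones(data.n)
    grid = synthesize_map(dtrue, ph)
    # direct summation on a small set of points: rho(x) ~ sum m|F|cos stuff
    rng = np.random.default_rng(0)
    pts = rng.random((40, 3))
    vals_fft = []
    vals_direct = []
    from friedel.maps import trilinear

    coeff = dtrue.f_mean * np.exp(1j * np.radians(truth.phi_p))
    for p in pts:
        vals_fft.append(trilinear(grid.values, p)[0])
        tot = 0.0
        for op in data.sg.ops:
            h_im = truth.hkl @ op.R
            shift = np.exp(-2j * np.pi * (truth.hkl @ op.t))
            term = coeff * shift * np.exp(-2j * np.pi * (h_im @ p))
            tot += 2.0 * np.real(term).sum()  # Friedel mate doubles the real part
        vals_direct.append(tot / data.cell.volume)
    assert np.corrcoef(vals_fft, vals_direct)[0, 1] > 0.95


def test_solvent_mask_count_and_symmetry(dm_setup):
    _, data, _, _, _, grid, mask, _, _ = dm_setup
    assert mask.sum() == round(0.45 * mask.size)
    # symmetry: mask invariant under the P21 screw
    from friedel.maps import transform_map

    moved = transform_map(mask.astype(float), data.sg.ops[1], grid.dims)
    assert (moved.astype(bool) == mask).mean() > 0.99


def test_solvent_mask_covers_atoms(toy50_case):
    """Map from true phases: atom positions land in the protein region."""
    st, data, truth, _, _ = toy50_case
    ph = PhaseDistribution(truth.hkl, np.zeros((len(truth.hkl), 4)),
                           truth.phi_p, np.ones(len(truth.hkl)), truth.centric)
    grid = synthesize_map(data, ph)
    mask = solvent_mask(grid, 0.4, data.d_min, sg=data.sg)
    dims = np.array(grid.dims)
    inside = 0
    total = 0
    for site in st.all_sites():
        for op in data.sg.ops:
            idx = tuple(np.round(np.mod(op.apply(site.frac), 1.0) * dims).astype(int) % dims)
            total += 1
            inside += not mask[idx]
    assert inside / total >= 0.8


def test_solvent_mask_validates_fraction(dm_setup):
    _, data, _, _, _, grid, *_ = dm_setup
    with pytest.raises(ValueError):
        solvent_mask(grid, 1.2, data.d_min)


def test_modify_density_identities(dm_setup):
    _, data, _, _, _, grid, mask, _, _ = dm_setup
    flat = modify_density(grid, mask, "flatten")
    again = modify_density(flat, mask, "flatten")
    assert np.allclose(flat.values, again.values)  # already-flat solvent
    flip0 = modify_density(grid, mask, "flip", flip_factor=0.0)
    assert np.allclose(flip0.values, flat.values)  # flip(0) == flatten
    flip1 = modify_density(grid, mask, "flip", flip_factor=1.0)
    restored = modify_density(flip1, mask, "flip", flip_factor=1.0)
    assert np.allclose(restored.values, grid.values)  # involution


def test_combine_uninformative_dm_channel_is_identity(dm_setup):
    _, data, _, em, phases, _, _, dm, _ = dm_setup
    em0 = estimate_comb_errors_cv(data, phases, dm, em)
    em0.d_dm = np.zeros(em0.n_shells)
    out = combine_phases_mlhl(phases, dm, em0, data)
    assert np.array_equal(out.phi_best, phases.phi_best)
    assert np.array_equal(out.fom, phases.fom)


def test_combine_flat_prior_follows_dm_phase(dm_setup):
    _, data, _, _, phases, _, _, dm, em_cv = dm_setup
    flat = PhaseDistribution(phases.hkl, np.zeros((phases.n, 4)),
                             np.zeros(phases.n), np.zeros(phases.n),
                             phases.centric)
    em_strong = estimate_comb_errors_cv(data, phases, dm, em_cv)
    em_strong.d_dm = np.full(em_strong.n_shells, 0.95)
    out = combine_phases_mlhl(flat, dm, em_strong, data)
    acent = ~data.centric & (out.fom > 0.3)
    dphi = np.abs((out.phi_best[acent] - dm.phi_dm[acent] + 180) % 360 - 180)
    assert np.median(dphi) < 5.0


def test_alpha_limits(dm_setup):
    """alpha = 1: experimental posterior unchanged; alpha = 0: equals MLHL."""
    _, data, _, _, phases, _, _, dm, em_cv = dm_setup
    em1 = estimate_comb_errors_cv(data, phases, dm, em_cv)
    em1.dm_corr = np.ones(em1.n_shells)
    out1 = combine_phases_multivariate(data, phases, dm, em1)
    assert np.max(np.abs(out1.phi_best - phases.phi_best)) < 1e-6
    assert np.max(np.abs(out1.fom - phases.fom)) < 1e-6
    assert np.max(np.abs(out1.hl - phases.hl)) < 1e-6
    em0 = estimate_comb_errors_cv(data, phases, dm, em_cv)
    em0.dm_corr = np.zeros(em0.n_shells)
    out0 = combine_phases_multivariate(data, phases, dm, em0)
    ref = combine_phases_mlhl(phases, dm, em0, data)
    assert np.max(np.abs(out0.phi_best - ref.phi_best)) < 1e-6
    assert np.max(np.abs(out0.fom - ref.fom)) < 1e-6


def test_alpha_out_of_range_rejected(dm_setup):
    _, data, _, _, phases, _, _, dm, em_cv = dm_setup
    em_bad = estimate_comb_errors_cv(data, phases, dm, em_cv)
    em_bad.dm_corr = np.full(em_bad.n_shells, 1.5)
    with pytest.raises(ValueError):
        combine_phases_multivariate(data, phases, dm, em_bad)


def test_cv_requires_free_set(toy50_case):
    st, data, truth, em, phases = toy50_case
    nofree = data.copy()
    nofree.free = np.zeros(data.n, dtype=bool)
    dims = suggest_grid_dims(data.cell, data.sg, data.d_min)
    grid = synthesize_map(nofree, phases, dims)
    dm = map_to_sf(grid, nofree)
    with pytest.raises(ValueError, match="free"):
        estimate_comb_errors_cv(nofree, phases, dm, em)


def test_cv_overfitting_direction(toy50_batch):
    """d_dm fitted on all/work reflections >= the free-set fit on average
    (feedback inflates the apparent map quality)."""
    diffs = []
    for st, data, truth, em, phases, _ in toy50_batch[:5]:
        dims = suggest_grid_dims(data.cell, data.sg, data.d_min)
        grid = synthesize_map(data, phases, dims, fom_weights=phases.fom * (~data.free))
        mask = solvent_mask(grid, 0.45, data.d_min, sg=data.sg)
        dm = map_to_sf(modify_density(grid, mask), data)
        em_cv = estimate_comb_errors_cv(data, phases, dm, em)
        diffs.append(np.mean(em_cv.d_dm) - np.mean(em_cv.d_dm_free))
    assert np.mean(diffs) >= 0.0


def test_noise_map_is_downweighted(dm_setup):
    """A DM channel of pure noise gets d_dm ~ 0."""
    _, data, _, em, phases, _, _, dm, _ = dm_setup
    rng = np.random.default_rng(8)
    from friedel.density import ModifiedMapSF

    noise_dm = ModifiedMapSF(dm.hkl, dm.f_dm, rng.uniform(0, 360, data.n))
    em_n = estimate_comb_errors_cv(data, phases, noise_dm, em)
    assert np.mean(em_n.d_dm_free) <= 0.1


def test_run_dm_cycles_validates_inputs(toy50_case):
    st, data, truth, em, phases = toy50_case
    with pytest.raises(ValueError):
        run_dm_cycles(data, phases, em, n_cycles=0)


def test_hand_determination_centrosymmetric_is_undetermined():
    """Single site at the origin in P1: both hands identical."""
    from conftest import make_small_crystal
    from friedel import SpaceGroup, generate_structure, simulate_dataset, ExperimentSpec, flag_free_set
    from friedel.simulate import Structure
    from conftest import SMALL_CELL

    base = generate_structure(5, SMALL_CELL, SpaceGroup("P1"), 40, [("Se", 1, -2.0, 4.0)])
    origin_site = Site("Se", 0.0, 0.0, 0.0, occ=1.0, b=20.0, f_prime=-2.0, f_dprime=4.0)
    st = Structure(base.cell, base.sg, base.light_atoms, Substructure([origin_site]))
    ds, truth = simulate_dataset(
        st, ExperimentSpec(kind="SAD", channels=[("p", -2.0, 4.0)], d_min=2.5,
                           noise_frac=0.05, seed=3)
    )
    data = flag_free_set(ds[0], 0.05, seed=4)
    from friedel.phasing import refine_error_model

    em = refine_error_model(data, st.heavy, max_iter=8, max_refl_per_shell=50)
    decision, stats = determine_hand(data, st.heavy, em, n_cycles=2)
    assert decision == "undetermined"
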
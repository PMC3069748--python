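"""Anomalous Patterson maps, substructure search, matching, termination."""

import numpy as np
import pytest

from friedel import Site, SpaceGroup, Substructure, UnitCell, invert_hand
from friedel.fa import FAEstimate, estimate_fa_multivariate, _normalize
from friedel.maps import trilinear
from friedel.patterson import (
    SearchConfig,
    TrialScore,
    anomalous_patterson,
    match_sites,
    score_substructure,
    search_substructure,
    should_terminate_early,
    align_substructure,
)
from friedel.reflections import assign_shells
from friedel.simulate import structure_factors_sites
from friedel.symmetry import min_image_distance, unique_reflections

from conftest import make_small_crystal


def _fa_from_truth(sub, cell, sg, d_min=2.5, n_shells=8):
    """FAEstimate built directly from the true heavy amplitudes."""
    hkl = unique_reflections(cell, sg, d_min)
    fp, fm = structure_factors_sites(sub.sites, cell, sg, hkl)
    fh = 0.5 * (np.abs(fp) + np.abs(fm))
    from friedel.reflections import ReflectionSet

    dummy = ReflectionSet(cell=cell, sg=sg, hkl=hkl, f_plus=fh + 1,
                          sig_plus=np.ones(len(hkl)), f_minus=fh + 1,
                          sig_minus=np.ones(len(hkl)),
                          centric=np.zeros(len(hkl), bool))
    shells = assign_shells(dummy, n_shells)
    use = ~sg.is_centric(hkl)
    e = _normalize(fh, use, shells)
    return FAEstimate(hkl, fh, np.ones(len(hkl)), e, use, "truth", cell, sg,
                      dummy.d, shells)


@pytest.fixture(scope="module")
def p21_truth_fa():
    cell = UnitCell(20, 24, 22)
    sg = SpaceGroup("P21")
    sub = Substructure([
        Site("Se", 0.13, 0.31, 0.57, occ=1.0, b=20.0, f_prime=-2.0, f_dprime=4.0),
        Site("Se", 0.62, 0.12, 0.20, occ=1.0, b=20.0, f_prime=-2.0, f_dprime=4.0),
    ])
    return cell, sg, sub, _fa_from_truth(sub, cell, sg)


def test_harker_section_peak_p21(p21_truth_fa):
    """Single-site Harker vector (2x, 1/2, 2z) carries a strong peak."""
    cell, sg, sub, fa = p21_truth_fa
    pmap = anomalous_patterson(fa)
    for s in sub.sites:
        u = np.mod([2 * s.x, 0.5, 2 * s.z], 1.0)
        val = trilinear(pmap.values, u)[0]
        assert val > 5.0 * pmap.sigma


def test_cross_vector_peaks_p1():
    cell = UnitCell(18, 18, 18)
    sg = SpaceGroup("P1")
    sub = Substructure([
        Site("Se", 0.15, 0.25, 0.35, f_dprime=4.0),
        Site("Se", 0.55, 0.45, 0.75, f_dprime=4.0),
    ])
    fa = _fa_from_truth(sub, cell, sg)
    pmap = anomalous_patterson(fa)
    u12 = np.mod(sub.sites[0].frac - sub.sites[1].frac, 1.0)
    for u in (u12, np.mod(-u12, 1.0)):
        assert trilinear(pmap.values, u)[0] > 5.0 * pmap.sigma


def test_flat_fa_gives_flat_patterson(p21_truth_fa):
    cell, sg, sub, fa = p21_truth_fa
    flat = FAEstimate(fa.hkl, np.ones(fa.n), fa.sig_fa, fa.e_norm, fa.use,
                      "flat", cell, sg, fa.d, fa.shell)
    flat.e_norm = _normalize(flat.fa, flat.use, flat.shell)
    pmap = anomalous_patterson(flat)
    assert pmap.values.max() <= 4.0 * max(pmap.sigma, 1e-12)


def test_patterson_symmetry_invariance(p21_truth_fa):
    """The map is invariant under the Patterson group (rotations + inversion)."""
    cell, sg, sub, fa = p21_truth_fa
    pmap = anomalous_patterson(fa)
    v = pmap.values
    # P21 Patterson symmetry 2/m: check the twofold along b and inversion
    rot = v[::-1, :, ::-1]
    rot = np.roll(rot, 1, axis=0)
    rot = np.roll(rot, 1, axis=2)
    assert np.max(np.abs(v - rot)) < 1e-6 * max(pmap.sigma, 1e-12)
    inv = np.roll(v[::-1, ::-1, ::-1], 1, axis=(0, 1, 2))
    assert np.max(np.abs(v - inv)) < 1e-6 * max(pmap.sigma, 1e-12)


def test_score_substructure_self_consistency(p21_truth_fa):
    cell, sg, sub, fa = p21_truth_fa
    assert score_substructure(sub, fa) >= 0.99


def test_score_substructure_null_distribution(p21_truth_fa):
    cell, sg, sub, fa = p21_truth_fa
    rng = np.random.default_rng(17)
    scores = []
    for _ in range(200):
        rnd = Substructure([
            Site("Se", *rng.random(3), f_dprime=4.0) for _ in range(2)
        ])
        scores.append(abs(score_substructure(rnd, fa)))
    assert np.quantile(scores, 0.95) < 0.3


def test_deleting_a_site_lowers_the_score(p21_truth_fa):
    cell, sg, sub, fa = p21_truth_fa
    partial = Substructure([sub.sites[0]])
    assert score_substructure(partial, fa) < score_substructure(sub, fa)


def test_search_recovers_sites_reference_toy(toy50_case):
    st, data, truth, _, _ = toy50_case
    fa = estimate_fa_multivariate(data)
    trials = search_substructure(fa, n_sites_expected=2, n_trials=2, seed=5,
                                 f_prime=-2.0, f_dprime=4.0)
    n, rows = match_sites(trials[0].sites, st.heavy, data.sg, data.cell, tol=0.5)
    assert n == 2


def test_search_reproducible_from_seed(toy50_case):
    st, data, _, _, _ = toy50_case
    fa = estimate_fa_multivariate(data)
    a = search_substructure(fa, n_sites_expected=2, n_trials=1, seed=9)
    b = search_substructure(fa, n_sites_expected=2, n_trials=1, seed=9)
    assert a[0].score == b[0].score
    assert np.allclose(a[0].sites.coords(), b[0].sites.coords())


def test_search_zero_signal_scores_low():
    _, data, _ = make_small_crystal(11, f_dprime=0.0)
    fa = estimate_fa_multivariate(data)
    trials = search_substructure(fa, n_sites_expected=2, n_trials=3, seed=2)
    assert trials[0].score < 0.3


def _scores(vals):
    return [TrialScore(i, 0, v, Substructure([Site("Se", 0.1, 0.1, 0.1, f_dprime=4.0)]))
            for i, v in enumerate(vals)]


def test_termination_by_score_threshold():
    assert should_terminate_early(_scores([0.9]), SearchConfig()) == "stop_success"


def test_termination_needs_deviation():
    assert should_terminate_early(_scores([0.3] * 5), SearchConfig()) == "continue"


def test_termination_by_deviation_rule():
    assert (
        should_terminate_early(_scores([0.55, 0.50, 0.30, 0.28, 0.25]), SearchConfig())
        == "stop_success"
    )


def test_termination_requires_a_trial():
    with pytest.raises(ValueError):
        should_terminate_early([], SearchConfig())


def test_match_sites_identity_origin_shift_and_hand(p21_truth_fa):
    cell, sg, sub, _ = p21_truth_fa
    n, rows = match_sites(sub, sub, sg, cell)
    assert n == 2 and max(r[2] for r in rows) < 1e-9
    # allowed origin shift (1/2, arbitrary y, 0)
    from dataclasses import replace

    shifted = Substructure([
        replace(s, x=(s.x + 0.5) % 1, y=(s.y + 0.1234) % 1) for s in sub.sites
    ])
    n, rows = match_sites(shifted, sub, sg, cell)
    assert n == 2 and max(r[2] for r in rows) < 1e-6
    # hand flip
    n, rows = match_sites(invert_hand(sub, sg), sub, sg, cell)
    assert n == 2 and max(r[2] for r in rows) < 1e-6


def test_align_substructure_returns_truth_frame(p21_truth_fa):
    cell, sg, sub, _ = p21_truth_fa
    from dataclasses import replace

    moved = Substructure([
        replace(s, x=(-s.x) % 1, y=(-s.y) % 1, z=(-s.z) % 1) for s in sub.sites
    ])
    aligned, n_ok, mean_d = align_substructure(moved, sub, sg, cell)
    assert n_ok == 2 and mean_d < 1e-6
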
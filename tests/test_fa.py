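"""|F_A| estimators, signal scores and channel selection."""

import numpy as np
import pytest

from friedel import ExperimentSpec, simulate_dataset
from friedel.fa import (
    anomalous_signal_by_shell,
    estimate_fa_isomorphous,
    estimate_fa_multivariate,
    estimate_fa_simple,
    fa_multivariate_core,
    fa_posterior_bruteforce,
    select_best_channel,
)

from conftest import make_small_crystal


@pytest.fixture(scope="module")
def sad_case():
    return make_small_crystal(3)


def test_simple_estimate_is_absolute_bijvoet_difference(sad_case):
    _, data, _ = sad_case
    est = estimate_fa_simple(data)
    i = np.flatnonzero(est.use)[0]
    assert est.fa[i] == pytest.approx(abs(data.f_plus[i] - data.f_minus[i]))
    assert not est.use[data.centric].any()


def test_simple_estimate_zero_without_anomalous_signal():
    _, data, _ = make_small_crystal(4, f_dprime=0.0, noise_frac=0.0)
    est = estimate_fa_simple(data)
    assert np.max(est.fa) < 1e-6


def test_normalization_unit_mean_square_per_shell(sad_case):
    _, data, _ = sad_case
    for est in (estimate_fa_simple(data), estimate_fa_multivariate(data)):
        for s in np.unique(est.shell):
            sel = est.use & (est.shell == s)
            if sel.sum() > 10:
                assert np.mean(est.e_norm[sel] ** 2) == pytest.approx(1.0, abs=0.05)


def test_multivariate_against_full_bruteforce_quadrature():
    """1-D-quadrature estimator vs the independent 3-D oracle (exact mate
    amplitudes, Rice observation terms, no difference reduction)."""
    rng = np.random.default_rng(11)
    sigma_n, heavy_fraction, r = 4000.0, 0.05, 0.12
    sigma_a = heavy_fraction * sigma_n
    M = 12
    a = np.sqrt(sigma_a / 2) * np.abs(rng.standard_normal(M) + 1j * rng.standard_normal(M))
    n = np.sqrt(sigma_n / 2) * np.abs(rng.standard_normal(M) + 1j * rng.standard_normal(M))
    th = rng.uniform(0, 2 * np.pi, M)
    tp = np.sqrt(n**2 + (r * a) ** 2 + 2 * r * a * n * np.sin(th))
    tm = np.sqrt(n**2 + (r * a) ** 2 - 2 * r * a * n * np.sin(th))
    sig = 0.05 * np.sqrt(sigma_n)
    fp = np.maximum(tp + rng.standard_normal(M) * sig, 0)
    fm = np.maximum(tm + rng.standard_normal(M) * sig, 0)
    est, _ = fa_multivariate_core(fp - fm, 2 * sig**2, sigma_a, r)
    oracle = np.array([
        fa_posterior_bruteforce(fp[i], fm[i], sig, sig, sigma_a, sigma_n, r, n_grid=100)
        for i in range(M)
    ])
    rel = (est - oracle) / oracle
    assert np.sqrt(np.mean(rel**2)) < 0.02


def test_multivariate_no_information_limit_is_rayleigh_mean():
    sigma_a = 25.0
    est, _ = fa_multivariate_core(np.array([0.0]), np.array([1e8]),
                                  np.array([sigma_a]), np.array([0.1]))
    assert est[0] == pytest.approx(np.sqrt(np.pi * sigma_a) / 2, rel=1e-6)


def test_multivariate_monotone_in_bijvoet_difference():
    dF = np.linspace(0, 30, 40)
    est, _ = fa_multivariate_core(dF, 8.0, 40.0, 0.12)
    assert np.all(np.diff(est) > -1e-9)
    assert np.all(est >= 0)


def test_multivariate_validates_inputs(sad_case):
    _, data, _ = sad_case
    with pytest.raises(ValueError):
        estimate_fa_multivariate(data, heavy_fraction=1.5)


def test_isomorphous_identical_sets_give_zero():
    _, data, _ = make_small_crystal(5)
    est = estimate_fa_isomorphous(data, data)
    assert np.max(est.fa) < 1e-9


def test_isomorphous_recovers_known_scale():
    _, data, _ = make_small_crystal(5)
    deriv = data.copy()
    deriv.f_plus = 2.0 * deriv.f_plus
    deriv.f_minus = 2.0 * deriv.f_minus
    est = estimate_fa_isomorphous(deriv, data)
    assert np.allclose(est.scale_per_shell, 2.0, rtol=0.01)


def test_isomorphous_requires_common_reflections():
    _, data, _ = make_small_crystal(5)
    tiny = data.copy()
    keep = np.arange(10)
    from friedel import ReflectionSet

    tiny = ReflectionSet(cell=data.cell, sg=data.sg, hkl=data.hkl[keep],
                         f_plus=data.f_plus[keep], sig_plus=data.sig_plus[keep],
                         f_minus=data.f_minus[keep], sig_minus=data.sig_minus[keep])
    with pytest.raises(ValueError, match="common"):
        estimate_fa_isomorphous(tiny, data)


def test_siras_isomorphous_estimate_tracks_heavy_amplitudes():
    """Zero-noise SIRAS: |F_deriv - k F_native| correlates with the true
    heavy amplitudes.  The correlation is capped by physics: the
    isomorphous difference is |F_H| |cos(phi_H - phi_P)|, and the |cos|
    modulation limits the Pearson correlation with |F_H| to ~0.7 even
    with perfect data."""
    from friedel import SpaceGroup, generate_structure
    from conftest import SMALL_CELL

    st = generate_structure(9, SMALL_CELL, SpaceGroup("P21"), 30, [("Se", 2, -2.0, 4.0)])
    ds, truth = simulate_dataset(
        st, ExperimentSpec(kind="SIRAS", channels=[("deriv", -2.0, 4.0)],
                           d_min=2.5, noise_frac=0.0, seed=3)
    )
    deriv = next(d for d in ds if d.label == "deriv")
    native = next(d for d in ds if d.label == "native")
    est = estimate_fa_isomorphous(deriv, native)
    fh = 0.5 * (np.abs(truth.f_h_plus["deriv"]) + np.abs(truth.f_h_minus["deriv"]))
    assert np.corrcoef(est.fa, fh)[0, 1] >= 0.65


def test_select_best_channel_prefers_stronger_anomalous_signal():
    from friedel import SpaceGroup, generate_structure
    from conftest import SMALL_CELL

    wins = 0
    for seed in range(3):
        st = generate_structure(20 + seed, SMALL_CELL, SpaceGroup("P21"), 40,
                                [("Se", 2, -2.0, 4.0)])
        ds, _ = simulate_dataset(
            st,
            ExperimentSpec(kind="MAD",
                           channels=[("weak", -2.0, 4.0), ("strong", -2.0, 6.0)],
                           d_min=2.5, noise_frac=0.05, seed=seed),
        )
        if select_best_channel([(d.label, d) for d in ds]) == "strong":
            wins += 1
    assert wins == 3


def test_select_best_channel_single_and_tiebreak(sad_case):
    _, data, _ = sad_case
    assert select_best_channel([("only", data)]) == "only"
    assert select_best_channel([("first", data), ("second", data.copy())]) == "first"
    with pytest.raises(ValueError):
        select_best_channel([])


def test_channel_selection_invariant_to_global_rescaling(sad_case):
    _, data, _ = sad_case
    scaled = data.copy()
    for f in ("f_plus", "sig_plus", "f_minus", "sig_minus"):
        setattr(scaled, f, 3.7 * getattr(scaled, f))
    assert select_best_channel([("a", data), ("b", scaled)]) == "a"  # tie-break


def test_signal_table_zero_for_friedel_symmetric_data():
    _, data, _ = make_small_crystal(4, f_dprime=0.0, noise_frac=0.0)
    table = anomalous_signal_by_shell(data, 5)
    assert np.allclose(table["bijvoet_ratio"], 0.0, atol=1e-10)


def test_signal_table_overall_row_is_count_weighted_recombination(sad_case):
    _, data, _ = sad_case
    table = anomalous_signal_by_shell(data, 6)
    shells = table[table["shell"] >= 0]
    overall = table[table["shell"] == -1].iloc[0]
    # recombine <|dF|> and <|F|> from the shells
    num = np.abs(data.delta_f).mean()
    den = data.f_mean.mean()
    assert overall["bijvoet_ratio"] == pytest.approx(num / den, rel=1e-9)
    assert shells["n"].sum() == data.n


def test_doubling_fdprime_doubles_bijvoet_ratio():
    # small f'' so the quadratic (f''^2) terms stay below the tolerance
    _, d1, _ = make_small_crystal(7, f_dprime=1.0, noise_frac=0.0)
    _, d2, _ = make_small_crystal(7, f_dprime=2.0, noise_frac=0.0)
    r1 = anomalous_signal_by_shell(d1, 1).iloc[-1]["bijvoet_ratio"]
    r2 = anomalous_signal_by_shell(d2, 1).iloc[-1]["bijvoet_ratio"]
    assert r2 / r1 == pytest.approx(2.0, rel=0.01)
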
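"""Substructure phasing from a joint likelihood of the observed Friedel pairs.

For each protein phase phi on a uniform grid the model structure factors
are F+-(phi) = Fbar exp(i phi) + d beta F_H(+-h), where Fbar is the
protein-amplitude proxy (Friedel mean for SAD, scaled native for SIRAS),
F_H the substructure structure factor and d the per-shell Luzzati
parameter.  The likelihood is the product of two Rice terms in |F+| and
|F-| evaluated jointly -- the Friedel-pair measurement errors are never
merged into a single sigma(dF).  A merged-dF Gaussian reference mode (the
approach of classical heavy-atom refinement programs) is provided for
comparison.

The Luzzati parameter is made identifiable as a correlation by rescaling
the model heavy structure factors to the anomalous power observed in the
data (beta = sqrt(Sigma_A_data / Sigma_model) per shell) and coupling the
unmodelled-heavy variance as 0.5 (1 - d^2) Sigma_A_data: a complete,
correct substructure refines d toward 1, half the substructure toward
sqrt(1/2), an unrelated one toward 0.  This is what makes the quick
"check mode" completeness test work.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import i0e, logsumexp

from .reflections import ErrorModel, PhaseDistribution, ReflectionSet, assign_shells
from .simulate import Substructure, TruthRecord, structure_factors_sites

_V_FLOOR = 1e-10


# ----------------------------------------------------------------------
# model ingredients


def heavy_structure_factors(sub: Substructure, data: ReflectionSet) -> tuple[np.ndarray, np.ndarray]:
    fp, fm = structure_factors_sites(sub.sites, data.cell, data.sg, data.hkl)
    return fp, fm


def anomalous_power_scale(
    data: ReflectionSet,
    f_h_plus: np.ndarray,
    f_h_minus: np.ndarray,
    shells: np.ndarray,
    n_shells: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-shell (beta, Sigma_A_data, Sigma_model).

    Sigma_model = <|F_H|^2> of the model.  The model-to-data power scale
    beta solves the first-order moment relation

        <dF_obs^2 - sig_d^2> = beta^2 q (Sigma_T - beta^2 Sigma_M)/Sigma_T

    where q = <|F_H(h) - F_H(-h)*|^2>/2 is the model's anomalous-
    difference power (a composition property, independent of whether the
    site positions are right), Sigma_T the total power and the
    (Sigma_P/Sigma_T) factor the attenuation of the anomalous lever arm
    by the heavy fraction of the total structure factor.  The returned
    sigma_a is the observed anomalous-difference power itself (the
    Bijvoet excess): the part of the signal the protein-amplitude
    nuisance cannot absorb, which the (1 - d^2) variance coupling must
    carry.
    """
    dF2 = data.delta_f**2
    sig_d2 = data.sig_plus**2 + data.sig_minus**2
    aniso = np.abs(f_h_plus - np.conj(f_h_minus)) ** 2 / 2.0
    sig_m = 0.5 * (np.abs(f_h_plus) ** 2 + np.abs(f_h_minus) ** 2)
    fbar = data.f_mean
    acent = ~data.centric
    beta = np.ones(n_shells)
    sigma_a = np.zeros(n_shells)
    sigma_model = np.zeros(n_shells)
    for s in range(n_shells):
        sel = (shells == s) & acent
        if sel.sum() == 0:
            continue
        sigma_model[s] = max(np.mean(sig_m[shells == s]), 1e-12)
        q = max(np.mean(aniso[sel]), 1e-12)
        sigma_t = max(np.mean(fbar[sel] ** 2) - 0.25 * np.mean(sig_d2[sel]), 1e-12)
        excess = np.mean(dF2[sel]) - np.mean(sig_d2[sel])
        excess = max(excess, 1e-4 * q)
        sigma_a[s] = excess
        # beta^2 from the quadratic, smaller root; heavy power capped at
        # 90% of the total
        acoef = q * sigma_model[s] / sigma_t
        disc = q * q - 4.0 * acoef * excess
        if disc > 0:
            b2 = (q - np.sqrt(disc)) / (2.0 * acoef)
        else:
            b2 = q / (2.0 * acoef)
        b2 = min(max(b2, 1e-6), 0.9 * sigma_t / sigma_model[s])
        beta[s] = np.sqrt(b2)
    return beta, sigma_a, sigma_model


def _log_rice(x: np.ndarray, nu: np.ndarray, var: np.ndarray) -> np.ndarray:
    """log Rice(x; nu, var) up to terms constant in nu and var.

    The Rice prefactor is x/var, so the variance normalization is a full
    -log(var), not the Gaussian -log(var)/2."""
    z = x * nu / var
    return -((x - nu) ** 2) / (2.0 * var) + np.log(i0e(z)) - np.log(var)


@dataclass
class PhasingModelData:
    """Precomputed arrays shared by posterior evaluation and refinement."""

    data: ReflectionSet
    shells: np.ndarray
    f_h_plus: np.ndarray
    f_h_minus: np.ndarray
    beta: np.ndarray
    sigma_a: np.ndarray
    sigma_p: np.ndarray  # per-shell protein (non-heavy) power
    f_p_est: np.ndarray  # protein-amplitude starting proxy per reflection
    extra_var_obs: np.ndarray = None  # e.g. native noise for SIRAS

    @property
    def n_shells(self) -> int:
        return len(self.beta)


def prepare_model(
    data: ReflectionSet,
    sub: Substructure,
    n_shells: int = 10,
    f_p_est: np.ndarray = None,
    extra_var_obs: np.ndarray = None,
) -> PhasingModelData:
    shells = assign_shells(data, n_shells)
    fhp, fhm = heavy_structure_factors(sub, data)
    beta, sigma_a, _ = anomalous_power_scale(data, fhp, fhm, shells, n_shells)
    if f_p_est is None:
        f_p_est = data.f_mean
    fbar2 = np.array(
        [np.mean(data.f_mean[shells == s] ** 2) if np.any(shells == s) else 1.0 for s in range(n_shells)]
    )
    sigma_p = np.maximum(fbar2 - sigma_a, 0.1 * fbar2)
    return PhasingModelData(data, shells, fhp, fhm, beta, sigma_a, sigma_p, f_p_est, extra_var_obs)


def _posterior_grid(
    model: PhasingModelData,
    d_shell: np.ndarray,
    var_extra_shell: np.ndarray,
    n_phi: int = 72,
    mode: str = "joint",
    subset: np.ndarray = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Log-likelihood on the phase grid for every (selected) reflection.

    Returns (phi_grid_rad, loglik (M, n_phi), marginal loglik (M,)).
    ``mode``: 'joint' (two Rice terms on the Friedel pair) or
    'gaussian_df' (one Gaussian on the merged Bijvoet difference).
    """
    data = model.data
    idx = np.arange(data.n) if subset is None else subset
    sh = model.shells[idx]
    d = d_shell[sh][:, None]
    ve = var_extra_shell[sh][:, None]
    sa = model.sigma_a[sh][:, None]
    beta = model.beta[sh][:, None]
    fp_est = model.f_p_est[idx][:, None]
    fhp = model.f_h_plus[idx][:, None]
    fhm_c = np.conj(model.f_h_minus[idx])[:, None]

    phi = np.linspace(0.0, 2.0 * np.pi, n_phi, endpoint=False)
    eip = np.exp(1j * phi)[None, :]
    heavy_p = d * beta * fhp
    heavy_m = d * beta * fhm_c

    # each mate carries +-dF/2 of any unmodelled anomalous signal
    var_model = 0.25 * (1.0 - d**2) * sa + ve
    if model.extra_var_obs is not None:
        var_model = var_model + model.extra_var_obs[idx][:, None]
    vp = data.sig_plus[idx][:, None] ** 2 + var_model + _V_FLOOR
    vm = data.sig_minus[idx][:, None] ** 2 + var_model + _V_FLOOR

    # The protein amplitude x is a nuisance: locate its conditional mode
    # per (reflection, phi) by Gauss-Newton on the two-mate misfit plus
    # the Rayleigh prior, then marginalize x with a short Gauss-Hermite
    # quadrature about the mode.
    fo_p = data.f_plus[idx][:, None]
    fo_m = data.f_minus[idx][:, None]
    a_p = np.real(heavy_p * np.conj(eip))
    a_m = np.real(heavy_m * np.conj(eip))
    c_p = np.abs(heavy_p) ** 2
    c_m = np.abs(heavy_m) ** 2
    fh2 = 0.5 * (c_p + c_m)
    sigma_p = np.maximum(model.sigma_p[sh][:, None], 1e-6)
    x_floor = 1e-3 * np.sqrt(sigma_p)

    def _newton(x0, n_iter=4):
        x = x0
        for _ in range(n_iter):
            amp_p = np.sqrt(np.maximum(x * x + 2 * x * a_p + c_p, 1e-20))
            amp_m = np.sqrt(np.maximum(x * x + 2 * x * a_m + c_m, 1e-20))
            gp = (x + a_p) / amp_p
            gm = (x + a_m) / amp_m
            grad = (amp_p - fo_p) * gp / vp + (amp_m - fo_m) * gm / vm + (
                2.0 * x / sigma_p - 1.0 / np.maximum(x, 1e-6)
            )
            curv = gp * gp / vp + gm * gm / vm + 2.0 / sigma_p
            x = np.clip(x - grad / curv, x_floor, None)
        amp_p = np.sqrt(np.maximum(x * x + 2 * x * a_p + c_p, 1e-20))
        amp_m = np.sqrt(np.maximum(x * x + 2 * x * a_m + c_m, 1e-20))
        gp = (x + a_p) / amp_p
        gm = (x + a_m) / amp_m
        curv = gp * gp / vp + gm * gm / vm + 2.0 / sigma_p
        return x, np.sqrt(2.0 / curv)

    x0 = np.sqrt(np.maximum(fp_est**2 - fh2, 1e-12)) * np.ones_like(a_p)
    x1, step1 = _newton(x0)
    # the amplitude fold |x e^{i phi} + H| admits a second positive root
    # mirrored about -abar when the heavy projection is negative
    abar = 0.5 * (a_p + a_m)
    x2, step2 = _newton(np.maximum(-2.0 * abar - x1, x_floor), n_iter=3)
    # smooth separation weight (a hard gate would make the likelihood
    # discontinuous in the model parameters and trap optimizers)
    sep_ratio = np.abs(x2 - x1) / np.maximum(np.maximum(step1, step2), 1e-12)

    def _node_ll(xn, rice: bool):
        amp_pn = np.sqrt(np.maximum(xn * xn + 2 * xn * a_p + c_p, 1e-20))
        amp_mn = np.sqrt(np.maximum(xn * xn + 2 * xn * a_m + c_m, 1e-20))
        prior = np.log(np.maximum(xn, 1e-300)) - xn * xn / sigma_p
        if rice:
            return (
                _log_rice(fo_p, amp_pn, vp) + _log_rice(fo_m, amp_mn, vm) + prior
            )
        v = data.sig_delta_f[idx][:, None] ** 2 + 2.0 * var_model + _V_FLOOR
        dmodel = amp_pn - amp_mn
        return (
            -((data.delta_f[idx][:, None] - dmodel) ** 2) / (2.0 * v)
            - 0.5 * np.log(v)
            + prior
        )

    if mode not in ("joint", "gaussian_df"):
        raise ValueError(f"unknown mode {mode!r}")
    rice = mode == "joint"
    nodes, weights = np.polynomial.hermite.hermgauss(7)
    stack = []
    gate2 = np.log(1.0 / (1.0 + np.exp(-8.0 * np.clip(sep_ratio - 1.0, -60.0, 60.0))))
    for t, w in zip(nodes, weights):
        xn = np.maximum(x1 + t * step1, 1e-6)
        stack.append(_node_ll(xn, rice) + np.log(w) + t * t + np.log(step1))
        xn2 = np.maximum(x2 + t * step2, 1e-6)
        stack.append(_node_ll(xn2, rice) + np.log(w) + t * t + np.log(step2) + gate2)
    ll = logsumexp(np.stack(stack), axis=0)
    marg = logsumexp(ll, axis=1) - np.log(n_phi)
    return phi, ll, marg


def hl_and_fom(posterior: np.ndarray, phi: np.ndarray = None) -> tuple[np.ndarray, float, float]:
    """(A, B, C, D), phi_best (deg), fom from a normalized posterior grid.

    HL coefficients by probability-weighted least squares of the
    log-posterior on {1, cos, sin, cos2, sin2}; centroid phase and fom
    directly from the grid.  A flat posterior returns zeros.
    """
    p = np.asarray(posterior, dtype=float)
    if phi is None:
        phi = np.linspace(0.0, 2.0 * np.pi, len(p), endpoint=False)
    p = np.maximum(p, 0.0)
    tot = p.sum()
    if tot <= 0:
        return np.zeros(4), 0.0, 0.0
    p = p / tot
    z = np.sum(p * np.exp(1j * phi))
    fom = float(np.abs(z))
    phi_best = float(np.degrees(np.angle(z)) % 360.0)
    logp = np.log(np.maximum(p, 1e-300))
    X = np.column_stack(
        [np.ones_like(phi), np.cos(phi), np.sin(phi), np.cos(2 * phi), np.sin(2 * phi)]
    )
    w = p + 1e-6
    W = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(X * W[:, None], logp * W, rcond=None)
    hl = coef[1:5]
    if np.max(np.abs(logp - logp.mean())) < 1e-9:  # flat
        hl = np.zeros(4)
        fom = 0.0
    return hl, phi_best, fom


def hl_fit_batch(p: np.ndarray, phi: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized :func:`hl_and_fom` over rows of normalized posteriors.

    Returns (hl (M,4), phi_best deg (M,), fom (M,))."""
    z = np.sum(p * np.exp(1j * phi)[None, :], axis=1)
    fom = np.abs(z)
    phi_best = np.degrees(np.angle(z)) % 360.0
    logp = np.log(np.maximum(p, 1e-300))
    X = np.column_stack(
        [np.ones_like(phi), np.cos(phi), np.sin(phi), np.cos(2 * phi), np.sin(2 * phi)]
    )
    w = p + 1e-6
    A = np.einsum("jk,mj,jl->mkl", X, w, X)
    b = np.einsum("jk,mj->mk", X, w * logp)
    coef = np.linalg.solve(A, b[..., None])[..., 0]
    hl = coef[:, 1:5]
    flat = np.ptp(logp, axis=1) < 1e-9
    hl[flat] = 0.0
    fom[flat] = 0.0
    return hl, phi_best, fom


def fom_from_hl(hl: np.ndarray, n_phi: int = 720) -> tuple[float, float]:
    """Centroid fom and phase implied by HL coefficients (quadrature)."""
    phi = np.linspace(0.0, 2 * np.pi, n_phi, endpoint=False)
    logp = hl[0] * np.cos(phi) + hl[1] * np.sin(phi) + hl[2] * np.cos(2 * phi) + hl[3] * np.sin(2 * phi)
    p = np.exp(logp - logp.max())
    p /= p.sum()
    z = np.sum(p * np.exp(1j * phi))
    return float(np.abs(z)), float(np.degrees(np.angle(z)) % 360.0)


def _centric_two_point(
    model: PhasingModelData,
    d_shell: np.ndarray,
    var_extra_shell: np.ndarray,
    idx: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Two-point posterior on the allowed centric phases.

    The centric protein structure factor is real along the allowed axis;
    it is marginalized over a signed-Gaussian (Wilson) prior on a 1-D
    grid, the sign of the posterior mass selecting between the two
    allowed phases.  Returns (hl (M,4), phi_best, fom, marginal loglik).
    """
    data = model.data
    sh = model.shells[idx]
    d = d_shell[sh]
    ve = var_extra_shell[sh]
    sa = model.sigma_a[sh]
    beta = model.beta[sh]
    sp = model.sigma_p[sh]
    phi_r = np.radians(data.sg.centric_phase_restriction(data.hkl[idx]))
    heavy = d * beta * model.f_h_plus[idx]
    var_model = 0.25 * (1.0 - d**2) * sa + ve
    if model.extra_var_obs is not None:
        var_model = var_model + model.extra_var_obs[idx]
    v = data.sig_plus[idx] ** 2 + var_model + _V_FLOOR

    nx = 96
    t = np.linspace(-4.0, 4.0, nx)  # units of sqrt(Sigma_P)
    x = np.sqrt(sp)[:, None] * t[None, :]
    amp = np.abs(x * np.exp(1j * phi_r)[:, None] + heavy[:, None])
    ll = _log_rice(data.f_plus[idx][:, None], amp, v[:, None]) - 0.5 * t[None, :] ** 2
    mx = ll.max(axis=1, keepdims=True)
    w = np.exp(ll - mx)
    wsum = w.sum(axis=1)
    p1 = np.where(t[None, :] >= 0, w, 0.0).sum(axis=1) / wsum
    p2 = 1.0 - p1
    marg_extra = mx[:, 0] + np.log(wsum / nx)
    fom = np.abs(p1 - p2)
    phi_best = np.degrees(np.where(p1 >= p2, phi_r, phi_r + np.pi)) % 360.0
    hlt = 0.5 * np.clip(
        np.log(np.maximum(p1, 1e-300)) - np.log(np.maximum(p2, 1e-300)), -30, 30
    )
    hl = np.zeros((len(idx), 4))
    hl[:, 0] = hlt * np.cos(phi_r)
    hl[:, 1] = hlt * np.sin(phi_r)
    return hl, phi_best, fom, marg_extra


def phase_posteriors(
    data: ReflectionSet,
    sub: Substructure,
    em: ErrorModel,
    n_phi: int = 72,
    mode: str = "joint",
    model: PhasingModelData = None,
) -> PhaseDistribution:
    """SAD phase probability distributions for every reflection.

    Acentric reflections get the full joint-Friedel posterior on the phase
    grid; centric reflections a two-point posterior on their allowed
    phases.  A zero heavy-atom vector yields a flat (uninformative)
    posterior for that reflection.
    """
    if n_phi < 72:
        raise ValueError("n_phi must be >= 72")
    if model is None:
        model = prepare_model(data, sub, em.n_shells)
    acent = np.flatnonzero(~data.centric)
    cent = np.flatnonzero(data.centric)
    hl = np.zeros((data.n, 4))
    phi_best = np.zeros(data.n)
    fom = np.zeros(data.n)
    if len(acent):
        phi, ll, _ = _posterior_grid(model, em.luzzati_d, em.var_extra, n_phi, mode, acent)
        ll = ll - ll.max(axis=1, keepdims=True)
        p = np.exp(ll)
        p /= p.sum(axis=1, keepdims=True)
        hl[acent], phi_best[acent], fom[acent] = hl_fit_batch(p, phi)
    if len(cent):
        hl[cent], phi_best[cent], fom[cent], _ = _centric_two_point(
            model, em.luzzati_d, em.var_extra, cent
        )
    return PhaseDistribution(data.hkl.copy(), hl, phi_best, fom, data.centric.copy())


def phase_posterior_sad(
    obs_index: int,
    data: ReflectionSet,
    sub: Substructure,
    em: ErrorModel,
    n_phi: int = 72,
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior masses on the phase grid for one reflection (by index).

    Convenience single-reflection view of :func:`phase_posteriors`;
    returns (phi_grid_rad, posterior masses summing to 1).
    """
    model = prepare_model(data, sub, em.n_shells)
    phi, ll, _ = _posterior_grid(
        model, em.luzzati_d, em.var_extra, n_phi, "joint", np.array([obs_index])
    )
    p = np.exp(ll[0] - ll[0].max())
    return phi, p / p.sum()


# ----------------------------------------------------------------------
# error-model refinement (Luzzati parameters)


def refine_error_model(
    data: ReflectionSet,
    sub: Substructure,
    em0: ErrorModel = None,
    n_shells: int = 10,
    n_phi: int = 72,
    max_iter: int = 20,
    use_work_only: bool = True,
    max_refl_per_shell: int = 120,
) -> ErrorModel:
    """Per-shell Luzzati d and variance inflation by maximum marginal
    likelihood (the phase and protein amplitude integrated out).

    Shells are independent, so each is optimized separately (Nelder-Mead
    on (d, var_extra/Sigma_A); d clamped to [0, 1]).  For speed each
    shell's objective uses at most ``max_refl_per_shell`` reflections
    (deterministic stride subsample).
    """
    if sub.n_sites == 0:
        raise ValueError("empty substructure")
    model = prepare_model(data, sub, n_shells)
    shells = model.shells
    work = ~data.free if use_work_only else np.ones(data.n, dtype=bool)
    d_out = np.zeros(n_shells)
    v_out = np.zeros(n_shells)
    ns = np.zeros(n_shells, dtype=int)
    d_bounds = np.zeros((n_shells, 2))
    for s in range(n_shells):
        sel = np.flatnonzero((shells == s) & work)
        ns[s] = len(sel)
        shell_sel = shells == s
        d_bounds[s] = (data.d[shell_sel].max(), data.d[shell_sel].min())
        if len(sel) == 0:
            continue
        if len(sel) > max_refl_per_shell:
            stride = int(np.ceil(len(sel) / max_refl_per_shell))
            sel = sel[::stride]
        scale = max(model.sigma_a[s], 1e-6)
        d0 = em0.luzzati_d[s] if em0 is not None and em0.n_shells == n_shells else 0.5
        v0 = em0.var_extra[s] / scale if em0 is not None and em0.n_shells == n_shells else 0.1

        def neg_ll(p, sel=sel, scale=scale):
            dd = np.full(n_shells, float(np.clip(p[0], 0.0, 1.0)))
            vv = np.full(n_shells, float(max(p[1], 0.0)) * scale)
            _, _, marg = _posterior_grid(model, dd, vv, n_phi, "joint", sel[~data.centric[sel]])
            tot = marg.sum()
            cen = sel[data.centric[sel]]
            if len(cen):
                _, _, _, marg_c = _centric_two_point(model, dd, vv, cen)
                tot += marg_c.sum()
            return -tot / len(sel)

        # multi-start: the landscape can have basins at low and high d
        starts = [np.array([d0, v0])] + [
            np.array([dd, 0.1]) for dd in (0.2, 0.6, 0.9) if abs(dd - d0) > 0.1
        ]
        starts.sort(key=neg_ll)
        res = minimize(
            neg_ll,
            starts[0],
            method="Nelder-Mead",
            options={"maxfev": max(2 * max_iter, 20), "xatol": 5e-3, "fatol": 1e-5},
        )
        d_out[s] = float(np.clip(res.x[0], 0.0, 1.0))
        v_out[s] = float(max(res.x[1], 0.0)) * scale
    return ErrorModel(
        shell_d_max=d_bounds[:, 0],
        shell_d_min=d_bounds[:, 1],
        luzzati_d=d_out,
        var_extra=v_out,
        shell_n=ns,
        sigma_a_data=model.sigma_a.copy(),
        beta=model.beta.copy(),
    )


def check_substructure_complete(
    data: ReflectionSet,
    sub: Substructure,
    threshold: float = 0.7,
    n_shells: int = 10,
    max_iter: int = 12,
) -> tuple[str, float]:
    """Quick check mode: refine the error model with a reduced iteration
    budget and call the substructure complete iff the average Luzzati
    parameter exceeds the threshold (default 0.7)."""
    em = refine_error_model(data, sub, n_shells=n_shells, max_iter=max_iter)
    avg = em.avg_luzzati
    return ("complete" if avg > threshold else "incomplete"), avg


def total_marginal_loglik(
    data: ReflectionSet,
    sub: Substructure,
    em: ErrorModel,
    n_phi: int = 72,
    subset: np.ndarray = None,
) -> float:
    model = prepare_model(data, sub, em.n_shells)
    idx = np.arange(data.n) if subset is None else np.asarray(subset)
    ac = idx[~data.centric[idx]]
    ce = idx[data.centric[idx]]
    tot = 0.0
    if len(ac):
        _, _, marg = _posterior_grid(model, em.luzzati_d, em.var_extra, n_phi, "joint", ac)
        tot += marg.sum()
    if len(ce):
        _, _, _, marg_c = _centric_two_point(model, em.luzzati_d, em.var_extra, ce)
        tot += marg_c.sum()
    return float(tot)


def refine_sites(
    data: ReflectionSet,
    sub: Substructure,
    em: ErrorModel,
    n_phi: int = 24,
    rounds: int = 2,
    n_subset: int = 1500,
    merge_dist: float = 1.0,
    max_iter: int = 60,
) -> Substructure:
    """Refine site coordinates, occupancies and B against the marginal
    likelihood (occ in (0, 2], B in [2, 100]).

    Sites closer than ``merge_dist`` A are merged (occupancies summed)
    first.  The error model is held at a fixed reference calibration
    (d capped at 0.9, a small variance floor replacing var_extra): letting
    the per-shell error parameters float would let them absorb the very
    model errors the refinement must see.  Sites are refined cyclically
    (coordinates by Nelder-Mead, then occupancy/B by bounded
    quasi-Newton) on a stride subsample of the reflections -- ranking by
    amplitude would discard the weak reflections that carry most of the
    anomalous leverage.  The returned substructure never scores a lower
    objective than the input (the input is kept otherwise).
    """
    from dataclasses import replace

    sub = _merge_close_sites(sub, data, merge_dist)
    em_ref = ErrorModel(
        shell_d_max=em.shell_d_max.copy(),
        shell_d_min=em.shell_d_min.copy(),
        luzzati_d=np.minimum(em.luzzati_d, 0.9),
        var_extra=0.05 * np.maximum(em.sigma_a_data, 1e-9),
        shell_n=em.shell_n.copy(),
        sigma_a_data=em.sigma_a_data.copy(),
        beta=em.beta.copy(),
    )
    stride = max(1, int(np.ceil(data.n / n_subset)))
    subset = np.arange(data.n)[::stride]
    sub_data = ReflectionSet(
        cell=data.cell, sg=data.sg, hkl=data.hkl[subset],
        f_plus=data.f_plus[subset], sig_plus=data.sig_plus[subset],
        f_minus=data.f_minus[subset], sig_minus=data.sig_minus[subset],
        centric=data.centric[subset], free=data.free[subset], label=data.label,
    )

    def obj(sites):
        return total_marginal_loglik(sub_data, Substructure(sites, sub.hand), em_ref, n_phi)

    cur = [replace(s) for s in sub.sites]
    for _ in range(rounds):
        for i in range(len(cur)):
            def neg_xyz(p, i=i):
                trial = list(cur)
                trial[i] = replace(cur[i], x=float(p[0] % 1.0), y=float(p[1] % 1.0),
                                   z=float(p[2] % 1.0))
                return -obj(trial)

            res = minimize(
                neg_xyz, [cur[i].x, cur[i].y, cur[i].z], method="Nelder-Mead",
                options={"maxfev": max_iter, "xatol": 2e-4, "fatol": 1e-4},
            )
            cur[i] = replace(cur[i], x=float(res.x[0] % 1.0), y=float(res.x[1] % 1.0),
                             z=float(res.x[2] % 1.0))

            def neg_ob(p, i=i):
                trial = list(cur)
                trial[i] = replace(cur[i], occ=float(np.clip(p[0], 0.01, 2.0)),
                                   b=float(np.clip(p[1] * 50.0, 2.0, 100.0)))
                return -obj(trial)

            res = minimize(
                neg_ob, [cur[i].occ, cur[i].b / 50.0], method="L-BFGS-B",
                bounds=[(0.01, 2.0), (0.04, 2.0)],
                options={"maxiter": max(max_iter // 6, 6), "eps": 1e-3},
            )
            cur[i] = replace(cur[i], occ=float(np.clip(res.x[0], 0.01, 2.0)),
                             b=float(np.clip(res.x[1] * 50.0, 2.0, 100.0)))
    refined = Substructure(cur, sub.hand)
    if obj(cur) < obj(sub.sites):
        return sub
    return refined


def _merge_close_sites(sub: Substructure, data: ReflectionSet, merge_dist: float) -> Substructure:
    from .symmetry import min_image_distance

    kept: list = []
    import warnings

    for site in sub.sites:
        merged = False
        for other in kept:
            if min_image_distance(data.cell, site.frac, other.frac) < merge_dist:
                other.occ = min(other.occ + site.occ, 2.0)
                merged = True
                warnings.warn("merged overlapping substructure sites", stacklevel=2)
                break
        if not merged:
            from dataclasses import replace

            kept.append(replace(site))
    return Substructure(kept, sub.hand)


# ----------------------------------------------------------------------
# SIRAS (uncorrelated) phasing


def phase_posteriors_siras(
    native: ReflectionSet,
    deriv: ReflectionSet,
    sub: Substructure,
    em: ErrorModel,
    n_phi: int = 72,
) -> PhaseDistribution:
    """Uncorrelated SIRAS posteriors: the native amplitude replaces the
    Friedel-mean protein proxy (per-shell scaled to the derivative), its
    measurement variance is added to both Rice terms, and the two error
    channels are treated as independent.  Reflections without a native
    mate fall back to the SAD posterior."""
    key_n = {tuple(h): i for i, h in enumerate(native.hkl)}
    f_p_est = deriv.f_mean.copy()
    extra = np.zeros(deriv.n)
    shells = assign_shells(deriv, em.n_shells)
    # per-shell scale native -> derivative
    fd_all, fn_all, sh_all, di_all, ni_all = [], [], [], [], []
    for i, h in enumerate(deriv.hkl):
        j = key_n.get(tuple(h))
        if j is not None:
            di_all.append(i)
            ni_all.append(j)
    di_all = np.array(di_all, dtype=int)
    ni_all = np.array(ni_all, dtype=int)
    k = np.ones(em.n_shells)
    for s in range(em.n_shells):
        sel = shells[di_all] == s
        if sel.sum():
            fn = native.f_mean[ni_all[sel]]
            fd = deriv.f_mean[di_all[sel]]
            if np.sum(fn**2) > 0:
                k[s] = float(np.sum(fd * fn) / np.sum(fn**2))
    ks = k[shells[di_all]]
    f_p_est[di_all] = ks * native.f_mean[ni_all]
    extra[di_all] = (ks * 0.5 * np.sqrt(native.sig_plus[ni_all] ** 2 + native.sig_minus[ni_all] ** 2)) ** 2
    model = prepare_model(deriv, sub, em.n_shells, f_p_est=f_p_est, extra_var_obs=extra)
    return phase_posteriors(deriv, sub, em, n_phi, "joint", model=model)


# ----------------------------------------------------------------------
# evaluation against simulator truth


def phase_quality_vs_truth(
    phases: PhaseDistribution,
    truth: TruthRecord,
    use_centric: bool = False,
) -> tuple[float, float, float]:
    """(mean cos phase error, fom-weighted mean |error| in degrees, map CC).

    Compared against the true protein phase on acentric reflections.  The
    map correlation is computed in reciprocal space (Parseval) between the
    fom-weighted synthesis and the true-phase synthesis with noise-free
    amplitudes.
    """
    key = {tuple(h): i for i, h in enumerate(truth.hkl)}
    rows = np.array([key[tuple(h)] for h in phases.hkl])
    sel = ~phases.centric if not use_centric else np.ones(phases.n, dtype=bool)
    dphi = np.radians(phases.phi_best[sel] - truth.phi_p[rows[sel]])
    mean_cos = float(np.mean(np.cos(dphi)))
    w = phases.fom[sel]
    abs_err = np.degrees(np.abs(np.angle(np.exp(1j * dphi))))
    fom_err = float(np.sum(w * abs_err) / max(np.sum(w), 1e-12))
    label = next(iter(truth.f_plus_true))
    famp = 0.5 * (truth.f_plus_true[label] + truth.f_minus_true[label])
    w1 = phases.fom * famp[rows] * np.exp(1j * np.radians(phases.phi_best))
    w2 = famp[rows] * np.exp(1j * np.radians(truth.phi_p[rows]))
    cc = np.real(np.sum(w1 * np.conj(w2))) / max(
        np.sqrt(np.sum(np.abs(w1) ** 2) * np.sum(np.abs(w2) ** 2)), 1e-12
    )
    return mean_cos, fom_err, float(cc)
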
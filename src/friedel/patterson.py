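"""Anomalous-difference Patterson substructure search.

The search replaces direct-methods/dual-space recycling engines with a
deterministic, seedable Patterson pipeline adequate for a handful of
sites: random translation candidates scored by the symmetry-minimum
function locate site 1 on the Harker vectors, further sites come from
Patterson-peak translations checked against cross-vectors, occupancies
are fit by least squares on the |F_A| estimates, and each trial is scored
by the correlation between normalized observed and calculated heavy-atom
amplitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, minimize

from .fa import FAEstimate, _normalize
from .maps import MapGrid, find_peaks, suggest_grid_dims, trilinear
from .simulate import Site, Substructure, invert_hand, structure_factors_sites
from .symmetry import SpaceGroup, UnitCell, min_image_distance


@dataclass
class TrialScore:
    """Outcome of one search trial."""

    trial_id: int
    seed: int
    score: float
    sites: Substructure


@dataclass
class SearchConfig:
    """Early-termination thresholds for multi-trial substructure search.

    stop when the best score reaches ``score_threshold``, or when at least
    ``min_trials`` trials are done, the best-worst spread exceeds
    ``deviation_threshold`` and the best score is at least ``min_best``.
    """

    score_threshold: float = 0.65
    deviation_threshold: float = 0.2
    min_trials: int = 5
    min_best: float = 0.4


def anomalous_patterson(
    fa: FAEstimate,
    cell: UnitCell = None,
    sg: SpaceGroup = None,
    d_min: float = None,
    grid_factor: float = 3.0,
) -> MapGrid:
    """Sharpened anomalous-difference Patterson map.

    P(u) = sum_h (E^2 - <E^2>) cos(2 pi h.u) over the unique reflections
    carrying |F_A| information, expanded to the Patterson symmetry of the
    space group (point-group rotations plus Friedel inversion).
    """
    cell = cell or fa.cell
    sg = sg or fa.sg
    if fa.n == 0 or not np.any(fa.use):
        raise ValueError("empty |F_A| estimate")
    if d_min is None:
        d_min = float(np.min(fa.d[fa.use]))
    dims = suggest_grid_dims(cell, sg, d_min, grid_factor)
    hkl = fa.hkl[fa.use]
    coeff = fa.e_norm[fa.use] ** 2
    coeff = coeff - coeff.mean()  # origin removal

    A = np.zeros(dims, dtype=complex)
    for op in sg.ops:
        for sign in (1, -1):
            im = sign * (hkl @ op.R)
            flat = np.ravel_multi_index((im % dims).T, dims)
            # assignment (not +=) so coincident orbit images are not
            # double-counted; coefficients within an orbit are identical
            A.flat[flat] = coeff
    P = np.real(np.fft.ifftn(A)) * np.prod(dims)
    return MapGrid(dims, cell, P)


def _harker_score(pmap: MapGrid, sg: SpaceGroup, x: np.ndarray) -> np.ndarray:
    """Symmetry-minimum function: min over non-identity ops of P(x - op x)."""
    x = np.atleast_2d(x)
    vals = None
    for op in sg.ops[1:]:
        u = x - (x @ op.R.T + op.t)
        v = trilinear(pmap.values, np.mod(u, 1.0))
        vals = v if vals is None else np.minimum(vals, v)
    if vals is None:
        vals = np.zeros(len(x))
    return vals


def _cross_score(pmap: MapGrid, sg: SpaceGroup, x: np.ndarray, existing: list) -> np.ndarray:
    """Minimum cross-vector Patterson value of candidate(s) x against all
    symmetry images of the existing sites, combined with the Harker score."""
    x = np.atleast_2d(x)
    vals = _harker_score(pmap, sg, x) if sg.n_ops > 1 else None
    for xj in existing:
        for op in sg.ops:
            u = x - (np.asarray(xj) @ op.R.T + op.t)
            v = trilinear(pmap.values, np.mod(u, 1.0))
            vals = v if vals is None else np.minimum(vals, v)
    return vals


def substructure_f_calc(
    sub: Substructure, fa: FAEstimate
) -> np.ndarray:
    """|F_H| of the substructure model at the estimate's reflections."""
    fp, fm = structure_factors_sites(sub.sites, fa.cell, fa.sg, fa.hkl)
    return 0.5 * (np.abs(fp) + np.abs(fm))


def score_substructure(sub: Substructure, fa: FAEstimate) -> float:
    """Pearson correlation of normalized observed and calculated heavy
    amplitudes over the estimate's used reflections."""
    if sub.n_sites == 0:
        raise ValueError("empty substructure")
    fh = substructure_f_calc(sub, fa)
    e_calc = _normalize(fh, fa.use, fa.shell)
    sel = fa.use
    a, b = fa.e_norm[sel], e_calc[sel]
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _make_sub(
    coords: np.ndarray,
    occs: np.ndarray,
    element: str,
    b: float,
    f_prime: float = 0.0,
    f_dprime: float = 0.0,
) -> Substructure:
    sites = [
        Site(element, *(np.mod(c, 1.0)), occ=float(np.clip(o, 0.01, 2.0)), b=b,
             f_prime=f_prime, f_dprime=f_dprime)
        for c, o in zip(np.atleast_2d(coords), occs)
    ]
    return Substructure(sites)


def _refine_trial(
    coords: np.ndarray,
    occs: np.ndarray,
    fa: FAEstimate,
    element: str,
    b_fixed: float,
    subset: np.ndarray,
    maxiter: int = 400,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Local refinement of site coordinates and relative occupancies by
    maximizing the correlation score on a reflection subset."""
    nsites = len(coords)
    fa_sub = FAEstimate(
        fa.hkl[subset], fa.fa[subset], fa.sig_fa[subset], fa.e_norm[subset],
        fa.use[subset], fa.method, fa.cell, fa.sg, fa.d[subset], fa.shell[subset],
    )

    def unpack(p):
        c = p[: 3 * nsites].reshape(nsites, 3)
        o = np.concatenate([[1.0], np.abs(p[3 * nsites :])]) if nsites > 1 else np.array([1.0])
        return c, o

    def neg_score(p):
        c, o = unpack(p)
        return -score_substructure(_make_sub(c, o, element, b_fixed), fa_sub)

    p0 = np.concatenate([coords.ravel(), occs[1:] / max(occs[0], 1e-6)])
    res = minimize(neg_score, p0, method="Nelder-Mead",
                   options={"maxiter": maxiter, "xatol": 1e-4, "fatol": 1e-5})
    c, o = unpack(res.x)
    return np.mod(c, 1.0), o, -res.fun


def search_substructure(
    fa: FAEstimate,
    cell: UnitCell = None,
    sg: SpaceGroup = None,
    n_sites_expected: int = 2,
    n_trials: int = 20,
    seed: int = 0,
    element: str = "Se",
    b_fixed: float = 20.0,
    f_prime: float = 0.0,
    f_dprime: float = 0.0,
    config: SearchConfig = None,
    d_min: float = None,
) -> list[TrialScore]:
    """Multi-trial Patterson search; returns trials sorted best-first.

    Reproducible from ``seed``; pass a :class:`SearchConfig` to stop early
    once :func:`should_terminate_early` fires.
    """
    if n_sites_expected < 1 or n_trials < 1:
        raise ValueError("n_sites_expected and n_trials must be >= 1")
    cell = cell or fa.cell
    sg = sg or fa.sg
    pmap = anomalous_patterson(fa, cell, sg, d_min=d_min)
    # candidate translations for secondary sites
    peaks = find_peaks(pmap, n_peaks=max(20, 4 * n_sites_expected),
                       exclude_origin_radius=1.5)
    n_eval = min(fa.n, 1500)
    # deterministic informative subset: strongest normalized amplitudes
    subset = np.argsort(-fa.e_norm * fa.use, kind="stable")[:n_eval]
    subset = np.sort(subset)

    trials: list[TrialScore] = []
    for t in range(n_trials):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), t]))
        cand = rng.random((96, 3))
        if sg.n_ops > 1:
            if sg.symbol == "P21":
                cand[:, 1] = 0.0  # origin free along the screw axis
            sc = _harker_score(pmap, sg, cand)
            x1 = cand[int(np.argmax(sc))]
            x1 = _local_max(pmap, sg, x1, [], cell)
        else:
            x1 = cand[0] if n_sites_expected > 1 else np.zeros(3)
        coords = [x1]
        for _ in range(1, n_sites_expected):
            best_val, best_x = -np.inf, None
            # candidate positions: symmetry images of known sites translated
            # by Patterson peak vectors (cross-vector relations hold against
            # every image, not just the identity one)
            for xj in coords:
                for op in sg.ops:
                    base = np.asarray(xj) @ op.R.T + op.t
                    for u in peaks:
                        for pm in (1.0, -1.0):
                            x2 = np.mod(base + pm * u, 1.0)
                            if any(
                                min_image_distance(cell, x2, xk) < 1.5 for xk in coords
                            ):
                                continue
                            v = float(_cross_score(pmap, sg, x2, coords)[0])
                            if v > best_val:
                                best_val, best_x = v, x2
            if best_x is None:
                best_x = rng.random(3)
            best_x = _local_max(pmap, sg, best_x, coords, cell)
            coords.append(best_x)
        coords = np.array(coords)
        occs = np.ones(len(coords))
        occs = _fit_occupancies(coords, occs, fa, element, b_fixed, subset)
        coords, occs, score = _refine_trial(coords, occs, fa, element, b_fixed, subset)
        sub = _make_sub(coords, occs, element, b_fixed, f_prime, f_dprime)
        score = score_substructure(sub, fa)  # full-set score, same for all trials
        trials.append(TrialScore(t, seed, score, sub))
        if config is not None and should_terminate_early(trials, config) == "stop_success":
            break
    return sorted(trials, key=lambda s: -s.score)


def _local_max(pmap, sg, x0, existing, cell, maxiter=60):
    """Refine a site position on the continuous Patterson score surface."""

    def neg(x):
        return -float(_cross_score(pmap, sg, np.mod(x, 1.0), existing)[0])

    if sg.n_ops == 1 and not existing:
        return np.mod(x0, 1.0)
    res = minimize(neg, x0, method="Nelder-Mead",
                   options={"maxiter": maxiter, "xatol": 1e-4})
    return np.mod(res.x, 1.0)


def _fit_occupancies(coords, occs, fa, element, b_fixed, subset):
    """Relative occupancies by least squares of normalized amplitudes."""
    nsites = len(coords)
    if nsites == 1:
        return occs
    sel = subset[fa.use[subset]]
    e_obs = fa.e_norm[sel]
    hkl = fa.hkl[sel]

    per_site = []
    for c in coords:
        fp, fm = structure_factors_sites(
            [Site(element, *c, occ=1.0, b=b_fixed)], fa.cell, fa.sg, hkl
        )
        per_site.append(0.5 * (fp + fm.conj()))  # same protein-phase frame
    per_site = np.array(per_site)

    def resid(o):
        f = np.abs(np.tensordot(np.concatenate([[1.0], o]), per_site, axes=1))
        ms = np.sqrt(np.mean(f**2))
        return f / max(ms, 1e-12) - e_obs

    res = least_squares(resid, occs[1:], bounds=(0.05, 2.0), max_nfev=60)
    return np.concatenate([[1.0], res.x])


def should_terminate_early(scores: list[TrialScore], config: SearchConfig = None) -> str:
    """Early-termination rule over completed trials.

    'stop_success' iff the best score reaches the threshold, or enough
    trials are done and a significant best-worst deviation exists with a
    non-trivial best score; 'continue' otherwise.
    """
    if not scores:
        raise ValueError("need at least one completed trial")
    config = config or SearchConfig()
    vals = [s.score for s in scores]
    best, worst = max(vals), min(vals)
    if best >= config.score_threshold:
        return "stop_success"
    if (
        len(vals) >= config.min_trials
        and best - worst >= config.deviation_threshold
        and best >= config.min_best
    ):
        return "stop_success"
    return "continue"


def match_sites(
    found: Substructure,
    truth: Substructure,
    sg: SpaceGroup,
    cell: UnitCell,
    tol: float = 0.5,
) -> tuple[int, list]:
    """Match found sites to truth under symmetry, allowed origin shifts and
    both hands; returns (n_matched within tol, mapping rows).

    Mapping rows are (found_idx, truth_idx, distance_A).  Greedy matching
    on the distance matrix; exhaustive over hand x anchor op x anchor
    pairing choices with continuous origin components solved from the
    anchor and discrete components snapped to allowed values.
    """
    best = _best_alignment(found, truth, sg, cell, tol)
    return best[0], best[1]


def _best_alignment(found, truth, sg, cell, tol=0.5, hands=("original", "inverted")):
    """Shared matcher: returns (n_ok, rows, total_dist, hand_name, op, shift)."""
    if found.n_sites == 0 or truth.n_sites == 0:
        raise ValueError("both substructures must be non-empty")
    tx = truth.coords()
    cont = np.array(sg.origin_continuous)

    best = (-1, [], np.inf, None, None, None)
    for hand_name, hand_sub in (
        ("original", found),
        ("inverted", invert_hand(found, sg)),
    ):
        if hand_name not in hands:
            continue
        fx = hand_sub.coords()
        for op in sg.ops:
            fx_op = np.mod(fx @ op.R.T + op.t, 1.0)
            # anchor choices determine the origin shift
            for i0 in range(len(fx_op)):
                for j0 in range(len(tx)):
                    delta = tx[j0] - fx_op[i0]
                    shift = np.where(cont, delta, np.round(delta * 2.0) / 2.0)
                    moved = np.mod(fx_op + shift, 1.0)
                    rows = _greedy_match(moved, tx, sg, cell)
                    n_ok = sum(1 for r in rows if r[2] <= tol)
                    total = sum(r[2] for r in rows)
                    if n_ok > best[0] or (n_ok == best[0] and total < best[2]):
                        best = (n_ok, rows, total, hand_name, op, shift)
    return best


def align_substructure(
    found: Substructure,
    truth: Substructure,
    sg: SpaceGroup,
    cell: UnitCell,
    allow_hand_flip: bool = True,
) -> tuple[Substructure, int, float]:
    """Map a found substructure into the frame of a reference one.

    Applies the (hand, symmetry op, allowed origin shift) combination
    that best matches the reference -- all of which are symmetries of the
    amplitude data, so the aligned model is crystallographically
    equivalent to the input.  Returns (aligned, n_matched_within_0.5A,
    mean distance of the matched pairs).
    """
    from dataclasses import replace

    hands = ("original", "inverted") if allow_hand_flip else ("original",)
    n_ok, rows, total, hand_name, op, shift = _best_alignment(
        found, truth, sg, cell, hands=hands
    )
    base = found if hand_name == "original" else invert_hand(found, sg)
    sites = []
    for s in base.sites:
        x = np.mod(np.asarray(s.frac) @ op.R.T + op.t + shift, 1.0)
        sites.append(replace(s, x=float(x[0]), y=float(x[1]), z=float(x[2])))
    aligned = Substructure(sites, "original")
    mean_d = total / max(len(rows), 1)
    return aligned, n_ok, mean_d


def _greedy_match(fx: np.ndarray, tx: np.ndarray, sg: SpaceGroup, cell: UnitCell) -> list:
    """Greedy bipartite matching; distances minimized over symmetry images."""
    dmat = np.full((len(fx), len(tx)), np.inf)
    for i, xi in enumerate(fx):
        for j, xj in enumerate(tx):
            for op in sg.ops:
                xi_img = np.mod(xi @ op.R.T + op.t, 1.0)
                dmat[i, j] = min(dmat[i, j], min_image_distance(cell, xi_img, xj))
    rows = []
    used_i, used_j = set(), set()
    flat = sorted(
        ((dmat[i, j], i, j) for i in range(len(fx)) for j in range(len(tx)))
    )
    for d, i, j in flat:
        if i in used_i or j in used_j:
            continue
        rows.append((i, j, float(d)))
        used_i.add(i)
        used_j.add(j)
    return rows
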
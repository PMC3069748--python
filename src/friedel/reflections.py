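"""Reflection containers and Bijvoet-difference statistics.

A :class:`ReflectionSet` holds one symmetry-unique observation per Miller
index as parallel numpy arrays (amplitudes, not intensities) together with
the cell/symmetry frame.  The per-reflection view :class:`AnomalousObservation`
exists for ergonomics; all heavy computation is array-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .symmetry import SpaceGroup, UnitCell, d_spacing


@dataclass(frozen=True)
class AnomalousObservation:
    """One Friedel pair: |F+|, |F-| with uncertainties."""

    hkl: tuple[int, int, int]
    f_plus: float
    sig_plus: float
    f_minus: float
    sig_minus: float
    centric: bool = False
    free: bool = False


@dataclass
class ReflectionSet:
    """Friedel-pair amplitudes for one wavelength in one cell/symmetry frame."""

    cell: UnitCell
    sg: SpaceGroup
    hkl: np.ndarray  # (N, 3) int
    f_plus: np.ndarray
    sig_plus: np.ndarray
    f_minus: np.ndarray
    sig_minus: np.ndarray
    centric: np.ndarray = None  # derived from sg if not given
    free: np.ndarray = None
    label: str = "data"
    d_min: float = field(default=None)
    d_max: float = field(default=None)

    def __post_init__(self) -> None:
        self.hkl = np.asarray(self.hkl, dtype=int).reshape(-1, 3)
        n = len(self.hkl)
        for name in ("f_plus", "sig_plus", "f_minus", "sig_minus"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have shape ({n},)")
            setattr(self, name, arr)
        if np.any(np.all(self.hkl == 0, axis=1)):
            raise ValueError("(0,0,0) not allowed in observation lists")
        if self.centric is None:
            self.centric = self.sg.is_centric(self.hkl)
        else:
            self.centric = np.asarray(self.centric, dtype=bool)
        if self.free is None:
            self.free = np.zeros(n, dtype=bool)
        else:
            self.free = np.asarray(self.free, dtype=bool)
        keys = {tuple(h) for h in self.hkl}
        if len(keys) != n:
            raise ValueError("duplicate Miller indices in observation list")
        if np.any(self.f_plus < 0) or np.any(self.f_minus < 0):
            raise ValueError("amplitudes must be non-negative")
        if np.any(self.sig_plus <= 0) or np.any(self.sig_minus <= 0):
            raise ValueError("sigmas must be positive")
        bad = self.centric & (
            (self.f_plus != self.f_minus) | (self.sig_plus != self.sig_minus)
        )
        if np.any(bad):
            raise ValueError("centric reflections must have identical Friedel mates")
        if n == 0:
            self.d_min = self.d_min or 0.0
            self.d_max = self.d_max or 0.0
            return
        d = self.d
        if self.d_min is None:
            self.d_min = float(d.min())
        if self.d_max is None:
            self.d_max = float(d.max())
        if d.min() < self.d_min - 1e-9 or d.max() > self.d_max + 1e-9:
            raise ValueError("observations outside stated resolution limits")

    @property
    def n(self) -> int:
        return len(self.hkl)

    @property
    def d(self) -> np.ndarray:
        return d_spacing(self.cell, self.hkl)

    @property
    def f_mean(self) -> np.ndarray:
        """Friedel-averaged amplitude (|F+| + |F-|) / 2."""
        return 0.5 * (self.f_plus + self.f_minus)

    @property
    def delta_f(self) -> np.ndarray:
        """Signed Bijvoet difference |F+| - |F-|."""
        return self.f_plus - self.f_minus

    @property
    def sig_delta_f(self) -> np.ndarray:
        return np.sqrt(self.sig_plus**2 + self.sig_minus**2)

    def observation(self, i: int) -> AnomalousObservation:
        return AnomalousObservation(
            tuple(int(v) for v in self.hkl[i]),
            float(self.f_plus[i]),
            float(self.sig_plus[i]),
            float(self.f_minus[i]),
            float(self.sig_minus[i]),
            bool(self.centric[i]),
            bool(self.free[i]),
        )

    def __iter__(self):
        return (self.observation(i) for i in range(self.n))

    def copy(self) -> "ReflectionSet":
        return ReflectionSet(
            cell=self.cell,
            sg=self.sg,
            hkl=self.hkl.copy(),
            f_plus=self.f_plus.copy(),
            sig_plus=self.sig_plus.copy(),
            f_minus=self.f_minus.copy(),
            sig_minus=self.sig_minus.copy(),
            centric=self.centric.copy(),
            free=self.free.copy(),
            label=self.label,
            d_min=self.d_min,
            d_max=self.d_max,
        )


def assign_shells(data: ReflectionSet, n_shells: int) -> np.ndarray:
    """Equal-population resolution shells, 0 = lowest resolution (largest d).

    Ties in d are broken by lexicographic hkl order so the binning is
    deterministic.
    """
    if n_shells < 1:
        raise ValueError("n_shells must be >= 1")
    d = data.d
    order = np.lexsort((data.hkl[:, 2], data.hkl[:, 1], data.hkl[:, 0], -d))
    shells = np.empty(data.n, dtype=int)
    bounds = np.linspace(0, data.n, n_shells + 1).astype(int)
    for s in range(n_shells):
        shells[order[bounds[s] : bounds[s + 1]]] = s
    return shells


@dataclass
class BijvoetStats:
    """Per-reflection Bijvoet differences and per-shell Bijvoet ratios."""

    delta_f: np.ndarray
    sig_delta_f: np.ndarray
    shell: np.ndarray
    shell_d_max: np.ndarray
    shell_d_min: np.ndarray
    shell_bijvoet_ratio: np.ndarray
    shell_n: np.ndarray
    overall_bijvoet_ratio: float


def compute_bijvoet_stats(data: ReflectionSet, n_shells: int = 10) -> BijvoetStats:
    """Signed dF, sigma(dF) and the Bijvoet ratio <|dF|>/<|F|> per shell.

    Centric reflections contribute dF = 0 by construction.  An all-centric
    input yields zero ratios rather than an error.
    """
    if data.n == 0:
        raise ValueError("empty reflection set")
    shells = assign_shells(data, n_shells)
    dF = data.delta_f
    fbar = data.f_mean
    d = data.d
    ratios = np.zeros(n_shells)
    dmax = np.zeros(n_shells)
    dmin = np.zeros(n_shells)
    ns = np.zeros(n_shells, dtype=int)
    for s in range(n_shells):
        sel = shells == s
        ns[s] = sel.sum()
        if ns[s] == 0:
            continue
        dmax[s] = d[sel].max()
        dmin[s] = d[sel].min()
        denom = fbar[sel].mean()
        ratios[s] = float(np.abs(dF[sel]).mean() / denom) if denom > 0 else 0.0
    denom = fbar.mean()
    overall = float(np.abs(dF).mean() / denom) if denom > 0 else 0.0
    return BijvoetStats(
        delta_f=dF,
        sig_delta_f=data.sig_delta_f,
        shell=shells,
        shell_d_max=dmax,
        shell_d_min=dmin,
        shell_bijvoet_ratio=ratios,
        shell_n=ns,
        overall_bijvoet_ratio=overall,
    )


def flag_free_set(data: ReflectionSet, fraction: float = 0.05, seed: int = 0, n_shells: int = 10) -> ReflectionSet:
    """Flag a stratified cross-validation (free) set, reproducible from seed.

    round(fraction * N) reflections are flagged, spread across
    equal-population resolution shells (per-shell counts within +-1 of
    fraction * shell size).
    """
    if not 0.0 < fraction < 0.5:
        raise ValueError("fraction must lie in (0, 0.5)")
    rng = np.random.default_rng(seed)
    shells = assign_shells(data, min(n_shells, data.n))
    free = np.zeros(data.n, dtype=bool)
    # largest-remainder allocation so the total matches round(fraction*N)
    target_total = int(round(fraction * data.n))
    sizes = np.bincount(shells, minlength=shells.max() + 1)
    quota = fraction * sizes
    base = np.floor(quota).astype(int)
    rem = quota - base
    short = target_total - base.sum()
    if short > 0:
        extra = np.argsort(-rem, kind="stable")[:short]
        base[extra] += 1
    for s, k in enumerate(base):
        idx = np.flatnonzero(shells == s)
        if k > 0 and len(idx) > 0:
            free[rng.choice(idx, size=min(k, len(idx)), replace=False)] = True
    out = data.copy()
    out.free = free
    return out


@dataclass
class PhaseDistribution:
    """Per-reflection Hendrickson-Lattman phase probabilities.

    P(phi) propto exp(A cos phi + B sin phi + C cos 2phi + D sin 2phi);
    phi_best is the circular centroid in degrees [0, 360) and fom the
    figure of merit |<exp(i phi)>|.
    """

    hkl: np.ndarray
    hl: np.ndarray  # (N, 4): A, B, C, D
    phi_best: np.ndarray  # degrees
    fom: np.ndarray
    centric: np.ndarray = None

    def __post_init__(self) -> None:
        self.hkl = np.asarray(self.hkl, dtype=int).reshape(-1, 3)
        self.hl = np.asarray(self.hl, dtype=float).reshape(-1, 4)
        self.phi_best = np.mod(np.asarray(self.phi_best, dtype=float), 360.0)
        self.fom = np.asarray(self.fom, dtype=float)
        if self.centric is None:
            self.centric = np.zeros(len(self.hkl), dtype=bool)
        if np.any(self.fom < -1e-9) or np.any(self.fom > 1 + 1e-9):
            raise ValueError("figure of merit must lie in [0, 1]")
        self.fom = np.clip(self.fom, 0.0, 1.0)

    @property
    def n(self) -> int:
        return len(self.hkl)

    def copy(self) -> "PhaseDistribution":
        return PhaseDistribution(
            self.hkl.copy(), self.hl.copy(), self.phi_best.copy(), self.fom.copy(), self.centric.copy()
        )


@dataclass
class ErrorModel:
    """Per-shell Luzzati parameters and variance terms.

    ``luzzati_d`` damps the (power-matched) heavy-atom model contribution;
    ``var_extra`` is a non-negative amplitude-scale variance inflation.
    ``d_dm`` and ``dm_corr`` (alpha) parameterize the density-modified map
    channel in phase combination: d_dm the SIGMAA-like quality of the DM
    phases, alpha the redundant-information fraction shared with the
    experimental channel.
    """

    shell_d_max: np.ndarray
    shell_d_min: np.ndarray
    luzzati_d: np.ndarray
    var_extra: np.ndarray
    shell_n: np.ndarray = None
    d_dm: np.ndarray = None
    dm_corr: np.ndarray = None
    sigma_a_data: np.ndarray = None  # estimated heavy-channel power per shell
    beta: np.ndarray = None  # model-to-data heavy power rescale per shell

    def __post_init__(self) -> None:
        ns = len(self.luzzati_d)
        self.luzzati_d = np.clip(np.asarray(self.luzzati_d, dtype=float), 0.0, 1.0)
        self.var_extra = np.maximum(np.asarray(self.var_extra, dtype=float), 0.0)
        if self.shell_n is None:
            self.shell_n = np.ones(ns, dtype=int)
        if self.d_dm is None:
            self.d_dm = np.zeros(ns)
        if self.dm_corr is None:
            self.dm_corr = np.zeros(ns)
        if self.sigma_a_data is None:
            self.sigma_a_data = np.zeros(ns)
        if self.beta is None:
            self.beta = np.ones(ns)

    @property
    def n_shells(self) -> int:
        return len(self.luzzati_d)

    @property
    def avg_luzzati(self) -> float:
        """Reflection-count-weighted mean of per-shell Luzzati D."""
        w = np.asarray(self.shell_n, dtype=float)
        return float(np.sum(w * self.luzzati_d) / np.sum(w))


def merge_friedel(
    hkl: np.ndarray,
    f: np.ndarray,
    sig: np.ndarray,
    cell: UnitCell,
    sg: SpaceGroup,
    label: str = "data",
    free: np.ndarray = None,
) -> ReflectionSet:
    """Build a ReflectionSet from per-hkl amplitude rows that may contain
    both mates of each pair: rows are mapped to the symmetry-unique
    representative and split into F+/F- by whether the original index maps
    with or without Friedel inversion."""
    hkl = np.asarray(hkl, dtype=int).reshape(-1, 3)
    store: dict[tuple, dict] = {}
    for i, h in enumerate(hkl):
        orbit = sg.equivalent_hkl(h)
        rep = max(orbit)
        # does h reach rep through a proper rotation (F+) or only with
        # Friedel inversion (F-)?
        plus = False
        for op in sg.ops:
            if tuple(int(v) for v in h @ op.R) == rep:
                plus = True
                break
        rec = store.setdefault(rep, {})
        side = "plus" if plus else "minus"
        if side in rec:
            raise ValueError(f"duplicate unique reflection {rep}")
        rec[side] = (float(f[i]), float(sig[i]), bool(free[i]) if free is not None else False)
    reps = sorted(store)
    fp, sp, fm, sm, fr = [], [], [], [], []
    cen = sg.is_centric(np.array(reps, dtype=int))
    for j, rep in enumerate(reps):
        rec = store[rep]
        if cen[j]:
            a = rec.get("plus") or rec.get("minus")
            b = rec.get("minus") or rec.get("plus")
            val = a if a is not None else b
            fp.append(val[0]); sp.append(val[1]); fm.append(val[0]); sm.append(val[1])
            fr.append(val[2])
        else:
            if "plus" not in rec or "minus" not in rec:
                raise ValueError(f"unpaired Friedel mate for reflection {rep}")
            fp.append(rec["plus"][0]); sp.append(rec["plus"][1])
            fm.append(rec["minus"][0]); sm.append(rec["minus"][1])
            fr.append(rec["plus"][2] or rec["minus"][2])
    return ReflectionSet(
        cell=cell, sg=sg, hkl=np.array(reps, dtype=int),
        f_plus=np.array(fp), sig_plus=np.array(sp),
        f_minus=np.array(fm), sig_minus=np.array(sm),
        free=np.array(fr, dtype=bool), label=label,
    )
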
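"""Synthetic toy crystals with deposited ground truth.

The simulator produces a small protein surrogate (light atoms, f'' = 0)
plus a few anomalous scatterers, computes exact direct-summation structure
factors with wavelength-dependent f'/f'', adds Gaussian amplitude noise
scaled per resolution shell, and records the ground truth (true protein
phases, heavy-atom structure factors, site list, noise-free amplitudes)
that every downstream stage is evaluated against.

Scattering model: single-Gaussian form factor f0(s) = Z * exp(-w s^2)
with s = 1/d and a per-element width w, Debye-Waller exp(-B s^2 / 4).
This keeps the resolution falloff of real form factors without shipping
Cromer-Mann tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .reflections import ReflectionSet, assign_shells
from .symmetry import (
    SpaceGroup,
    UnitCell,
    d_spacing,
    min_image_distance,
    unique_reflections,
)

# element -> (electron count Z, form-factor width w in A^2)
FORM_FACTORS: dict[str, tuple[float, float]] = {
    "C": (6.0, 3.0),
    "N": (7.0, 2.8),
    "O": (8.0, 2.6),
    "S": (16.0, 2.0),
    "Se": (34.0, 1.6),
    "Br": (35.0, 1.6),
    "Fe": (26.0, 1.7),
    "Hg": (80.0, 1.2),
}
_DEFAULT_WIDTH = 2.5


@dataclass
class Site:
    """One scatterer: fractional position, occupancy, B, scattering terms."""

    element: str
    x: float
    y: float
    z: float
    occ: float = 1.0
    b: float = 20.0
    f0_z: float = None
    f0_width: float = None
    f_prime: float = 0.0
    f_dprime: float = 0.0

    def __post_init__(self) -> None:
        if self.f0_z is None or self.f0_width is None:
            z, w = FORM_FACTORS.get(self.element, (6.0, _DEFAULT_WIDTH))
            if self.f0_z is None:
                self.f0_z = z
            if self.f0_width is None:
                self.f0_width = w
        if not 0.0 < self.occ <= 2.0:
            raise ValueError("occupancy must lie in (0, 2]")
        if self.b < 0:
            raise ValueError("B-factor must be non-negative")
        if self.f_dprime < 0:
            raise ValueError("f'' must be non-negative")

    @property
    def frac(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass
class Substructure:
    """Anomalous-scatterer model with a hand tag."""

    sites: list
    hand: str = "original"

    def __post_init__(self) -> None:
        if self.hand not in ("original", "inverted"):
            raise ValueError("hand must be 'original' or 'inverted'")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def coords(self) -> np.ndarray:
        return np.array([s.frac for s in self.sites]).reshape(-1, 3)

    def copy(self) -> "Substructure":
        return Substructure([replace(s) for s in self.sites], self.hand)


@dataclass
class Structure:
    """Simulator truth container: cell, symmetry, light atoms, heavy sites."""

    cell: UnitCell
    sg: SpaceGroup
    light_atoms: list
    heavy: Substructure

    def all_sites(self) -> list:
        return list(self.light_atoms) + list(self.heavy.sites)


@dataclass
class ExperimentSpec:
    """Which experiment the simulator emulates.

    channels: per-wavelength (label, f', f'') applied to the heavy sites.
    SIRAS adds a native set computed without the heavy sites.
    """

    kind: str = "SAD"
    channels: list = field(default_factory=lambda: [("peak", -2.0, 4.0)])
    native: bool = False
    d_min: float = 2.2
    noise_frac: float = 0.05
    seed: int = 0
    n_shells: int = 10

    def __post_init__(self) -> None:
        if self.kind not in ("SAD", "MAD", "SIRAS"):
            raise ValueError("kind must be SAD, MAD or SIRAS")
        if self.kind == "MAD" and len(self.channels) < 2:
            raise ValueError("MAD requires at least two channels")
        if self.kind == "SAD" and len(self.channels) != 1:
            raise ValueError("SAD takes exactly one channel")
        if self.noise_frac < 0:
            raise ValueError("noise_frac must be non-negative")
        if self.kind == "SIRAS":
            self.native = True


@dataclass
class TruthRecord:
    """Ground truth stored alongside a simulated dataset."""

    hkl: np.ndarray
    phi_p: np.ndarray  # true protein (light-atom) phase, degrees
    phi_total: dict  # per channel label: true total phase of F+, degrees
    f_h_plus: dict  # per channel label: complex heavy-atom F(h)
    f_h_minus: dict  # per channel label: complex heavy-atom F(-h)
    f_plus_true: dict  # per channel label: noise-free |F+|
    f_minus_true: dict
    f_native_true: np.ndarray = None
    sites: Substructure = None
    centric: np.ndarray = None


def generate_structure(
    seed: int,
    cell: UnitCell,
    sg: SpaceGroup,
    n_light: int,
    heavy_spec: list,
    min_light_dist: float = 1.5,
    min_heavy_dist: float = 3.0,
    max_attempts: int = 2000,
) -> Structure:
    """Random toy structure, reproducible from seed.

    Light atoms (carbon surrogate, f''=0) are placed uniformly in an
    asymmetric unit with B uniform in [10, 30] A^2 and pairwise separation
    >= 1.5 A; heavy sites get B in [15, 25] A^2 and separation >= 3 A.
    heavy_spec rows are (element, count, f_prime, f_dprime).
    """
    if n_light < 0 or any(c < 1 for _, c, _, _ in heavy_spec):
        raise ValueError("counts must be non-negative (heavy counts >= 1)")
    rng = np.random.default_rng(seed)
    asu_upper = {"P1": (1.0, 1.0, 1.0), "P21": (1.0, 0.5, 1.0), "P212121": (0.5, 0.5, 1.0)}[sg.symbol]

    ortho = cell.orthogonalization_matrix()

    def draw(min_dist: float, against_all: list) -> np.ndarray:
        others = np.array(against_all).reshape(-1, 3)
        for _ in range(max_attempts):
            x = rng.random(3) * np.array(asu_upper)
            if len(others) == 0:
                return x
            # every symmetry image of the candidate vs all placed atoms,
            # under the nearest lattice translation
            ok = True
            for op in sg.ops:
                delta = np.mod(op.apply(x), 1.0)[None, :] - others
                delta -= np.round(delta)
                cart = delta @ ortho.T
                if np.min(np.einsum("ij,ij->i", cart, cart)) < min_dist * min_dist:
                    ok = False
                    break
            if ok:
                return x
        raise RuntimeError("packing impossible at requested counts/spacing")

    heavy_sites: list[Site] = []
    heavy_pos: list[np.ndarray] = []
    for element, count, fp, fdp in heavy_spec:
        for _ in range(count):
            x = draw(min_heavy_dist, heavy_pos)
            b = rng.uniform(15.0, 25.0)
            heavy_sites.append(
                Site(element, *x, occ=1.0, b=b, f_prime=fp, f_dprime=fdp)
            )
            heavy_pos.append(x)
    light_sites: list[Site] = []
    light_pos: list[np.ndarray] = []
    for _ in range(n_light):
        x = draw(min_light_dist, light_pos + heavy_pos)
        b = rng.uniform(10.0, 30.0)
        light_sites.append(Site("C", *x, occ=1.0, b=b))
        light_pos.append(x)
    return Structure(cell, sg, light_sites, Substructure(heavy_sites))


def structure_factors_sites(
    sites: list,
    cell: UnitCell,
    sg: SpaceGroup,
    hkl: np.ndarray,
    f_prime_override: float = None,
    f_dprime_override: float = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact direct-summation F(h) and F(-h) for a site list.

    F(h) = sum_sites sum_ops (f0(s) + f' + i f'') occ exp(-B s^2/4)
           exp(2 pi i h.(R x + t)),   f0(s) = Z exp(-w s^2), s = 1/d.
    """
    hkl = np.asarray(hkl, dtype=int).reshape(-1, 3)
    n = len(hkl)
    if n == 0:
        return np.zeros(0, dtype=complex), np.zeros(0, dtype=complex)
    s2 = (1.0 / d_spacing(cell, hkl)) ** 2
    f_plus = np.zeros(n, dtype=complex)
    f_minus = np.zeros(n, dtype=complex)
    for site in sites:
        fp = site.f_prime if f_prime_override is None else f_prime_override
        fdp = site.f_dprime if f_dprime_override is None else f_dprime_override
        f_at_s = site.f0_z * np.exp(-site.f0_width * s2) + fp + 1j * fdp
        radial = site.occ * np.exp(-site.b * s2 / 4.0) * f_at_s
        for op in sg.ops:
            xeq = op.apply(site.frac)
            # wrap the phase argument to keep trig round-off at machine level
            phase = 2.0 * np.pi * np.mod(hkl @ xeq, 1.0)
            f_plus += radial * np.exp(1j * phase)
            f_minus += radial * np.exp(-1j * phase)
    return f_plus, f_minus


def structure_factors(
    structure: Structure,
    d_min: float,
    channel: tuple = None,
    hkl: np.ndarray = None,
    include_heavy: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(hkl, F(h), F(-h)) over the symmetry-unique set to d_min.

    ``channel`` is an optional (label, f', f'') triple overriding the
    anomalous corrections of the heavy sites (light atoms keep f''=0).
    """
    if hkl is None:
        if d_min <= 0:
            raise ValueError("d_min must be positive")
        hkl = unique_reflections(structure.cell, structure.sg, d_min)
    sites = list(structure.light_atoms)
    fpo = fdo = None
    if include_heavy:
        heavy = structure.heavy.sites
        if channel is not None:
            _, fpo, fdo = channel
        sites = sites + list(heavy)
    if channel is None:
        f_plus, f_minus = structure_factors_sites(sites, structure.cell, structure.sg, hkl)
    else:
        # split so overrides touch only the anomalous scatterers
        f_plus, f_minus = structure_factors_sites(
            structure.light_atoms, structure.cell, structure.sg, hkl
        )
        if include_heavy:
            hp, hm = structure_factors_sites(
                structure.heavy.sites, structure.cell, structure.sg, hkl,
                f_prime_override=fpo, f_dprime_override=fdo,
            )
            f_plus = f_plus + hp
            f_minus = f_minus + hm
    return hkl, f_plus, f_minus


def invert_hand(sub: Substructure, sg: SpaceGroup) -> Substructure:
    """The enantiomorphic substructure (x -> -x mod 1, hand tag toggled)."""
    flipped = []
    for s in sub.sites:
        x = sg.enantiomorph_action(s.frac)
        flipped.append(replace(s, x=float(x[0]), y=float(x[1]), z=float(x[2])))
    return Substructure(flipped, "inverted" if sub.hand == "original" else "original")


def simulate_dataset(structure: Structure, spec: ExperimentSpec) -> tuple[list, TruthRecord]:
    """Simulate observed Friedel-pair amplitudes plus the TruthRecord.

    Noise: independent Gaussian on each mate's amplitude with
    sigma = noise_frac * <|F|>_shell; sigma columns carry the generating
    sigma.  Centric reflections receive one draw shared by both mates.
    """
    cell, sg = structure.cell, structure.sg
    hkl = unique_reflections(cell, sg, spec.d_min)
    centric = sg.is_centric(hkl)
    _, fl_p, _ = structure_factors(structure, spec.d_min, hkl=hkl, include_heavy=False)
    phi_p = np.degrees(np.angle(fl_p)) % 360.0

    rng = np.random.default_rng(spec.seed)
    datasets = []
    phi_total: dict = {}
    fhp_d: dict = {}
    fhm_d: dict = {}
    ftp_d: dict = {}
    ftm_d: dict = {}

    def add_noise(fp_true: np.ndarray, fm_true: np.ndarray, label: str,
                  single_measurement: bool = False) -> ReflectionSet:
        # shell-scaled sigma from the noise-free amplitudes
        tmp = ReflectionSet(
            cell=cell, sg=sg, hkl=hkl,
            f_plus=fp_true, sig_plus=np.ones_like(fp_true),
            f_minus=fm_true, sig_minus=np.ones_like(fm_true),
            centric=centric, label=label,
        )
        shells = assign_shells(tmp, spec.n_shells)
        fbar = 0.5 * (fp_true + fm_true)
        shell_mean = np.array([fbar[shells == s].mean() for s in range(spec.n_shells)])
        sigma = np.maximum(spec.noise_frac * shell_mean[shells], 1e-9)
        # noise_frac = 0 must reproduce the noise-free amplitudes exactly
        # (the 1e-9 floor only keeps the sigma columns positive)
        draw_scale = sigma if spec.noise_frac > 0 else 0.0
        noise_p = rng.standard_normal(len(hkl)) * draw_scale
        noise_m = rng.standard_normal(len(hkl)) * draw_scale
        noise_m[centric] = noise_p[centric]
        if single_measurement:  # e.g. a native set: one amplitude per hkl
            noise_m = noise_p
        fp_obs = np.maximum(fp_true + noise_p, 0.0)
        fm_obs = np.maximum(fm_true + noise_m, 0.0)
        fm_obs[centric] = fp_obs[centric]
        return ReflectionSet(
            cell=cell, sg=sg, hkl=hkl,
            f_plus=fp_obs, sig_plus=sigma,
            f_minus=fm_obs, sig_minus=sigma.copy(),
            centric=centric, label=label,
        )

    for label, fp, fdp in spec.channels:
        hp, hm = structure_factors_sites(
            structure.heavy.sites, cell, sg, hkl,
            f_prime_override=fp, f_dprime_override=fdp,
        )
        f_plus = fl_p + hp
        f_minus = np.conj(fl_p) + hm
        fp_true, fm_true = np.abs(f_plus), np.abs(f_minus)
        # centric mates are symmetry-equivalent: enforce exactly
        fm_true[centric] = fp_true[centric]
        datasets.append(add_noise(fp_true, fm_true, label))
        phi_total[label] = np.degrees(np.angle(f_plus)) % 360.0
        fhp_d[label], fhm_d[label] = hp, hm
        ftp_d[label], ftm_d[label] = fp_true, fm_true

    f_native_true = None
    if spec.native:
        fn_true = np.abs(fl_p)
        f_native_true = fn_true
        datasets.append(add_noise(fn_true, fn_true.copy(), "native", single_measurement=True))

    truth = TruthRecord(
        hkl=hkl, phi_p=phi_p, phi_total=phi_total,
        f_h_plus=fhp_d, f_h_minus=fhm_d,
        f_plus_true=ftp_d, f_minus_true=ftm_d,
        f_native_true=f_native_true,
        sites=structure.heavy.copy(), centric=centric,
    )
    return datasets, truth


# ----------------------------------------------------------------------
# Default toy problem: a P21 crystal small enough for seconds-scale runs
# but with realistic anomalous signal levels (2 Se-like sites, f''=4,
# Bijvoet ratio ~5-7%).


def toy50_structure(seed: int = 0) -> Structure:
    """The package's reference toy crystal: P21, 34x42x38 A, 150 light
    atoms, 2 Se sites (f' = -2, f'' = 4)."""
    cell = UnitCell(34.0, 42.0, 38.0, 90.0, 90.0, 90.0)
    sg = SpaceGroup("P21")
    return generate_structure(seed, cell, sg, 150, [("Se", 2, -2.0, 4.0)])


def toy50_sad_spec(seed: int = 0, noise_frac: float = 0.05, d_min: float = 2.2) -> ExperimentSpec:
    return ExperimentSpec(
        kind="SAD", channels=[("peak", -2.0, 4.0)], d_min=d_min,
        noise_frac=noise_frac, seed=seed,
    )


def simulate_toy50(seed: int = 0, noise_frac: float = 0.05) -> tuple[Structure, ReflectionSet, TruthRecord]:
    """One-call toy50 SAD simulation (structure seed and noise seed tied)."""
    structure = toy50_structure(seed)
    datasets, truth = simulate_dataset(structure, toy50_sad_spec(seed + 1000003, noise_frac))
    return structure, datasets[0], truth
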
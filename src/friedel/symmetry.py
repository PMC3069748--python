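"""Unit cells, space-group operators and reflection geometry.

The package deliberately supports a small, hard-coded set of space groups
(P1, P21, P212121): enough to exercise acentric phasing, Harker sections,
centric zones, and the origin/hand ambiguities that matter for anomalous
phasing, without pulling in a full symmetry library.

Conventions: fractional coordinates throughout; Miller indices are integer
triples; phases are degrees at module boundaries and radians internally.
A symmetry operation acts on coordinates as ``x' = R @ x + t`` and on a
Miller index (row vector) as ``h' = h @ R``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class UnitCell:
    """Crystal unit cell (lengths in Angstrom, angles in degrees)."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must lie in (0, 180) degrees")
        if np.linalg.det(self.metric_tensor()) <= 0:
            raise ValueError("cell metric tensor is not positive definite")

    def metric_tensor(self) -> np.ndarray:
        """Real-space metric tensor G (3x3), in A^2."""
        ca, cb, cg = (np.cos(np.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        a, b, c = self.a, self.b, self.c
        return np.array(
            [
                [a * a, a * b * cg, a * c * cb],
                [a * b * cg, b * b, b * c * ca],
                [a * c * cb, b * c * ca, c * c],
            ]
        )

    def reciprocal_metric_tensor(self) -> np.ndarray:
        return np.linalg.inv(self.metric_tensor())

    @property
    def volume(self) -> float:
        return float(np.sqrt(np.linalg.det(self.metric_tensor())))

    def orthogonalization_matrix(self) -> np.ndarray:
        """Matrix M with cartesian = M @ fractional (Cholesky of G)."""
        return np.linalg.cholesky(self.metric_tensor()).T

    def lengths(self) -> tuple[float, float, float]:
        return (self.a, self.b, self.c)


@dataclass(frozen=True)
class SymOp:
    """One symmetry operation: integer rotation matrix plus fractional shift."""

    rot: tuple[tuple[int, ...], ...]
    trans: tuple[float, float, float]

    @property
    def R(self) -> np.ndarray:
        return np.array(self.rot, dtype=int)

    @property
    def t(self) -> np.ndarray:
        return np.array(self.trans, dtype=float)

    def apply(self, x: np.ndarray) -> np.ndarray:
        return (self.R @ np.asarray(x, dtype=float).T).T + self.t


def _op(rot, trans=(0.0, 0.0, 0.0)) -> SymOp:
    return SymOp(tuple(tuple(int(v) for v in row) for row in rot), tuple(float(v) for v in trans))


_I = ((1, 0, 0), (0, 1, 0), (0, 0, 1))

# Hard-coded operator tables; closure is unit-tested.
_SG_TABLE: dict[str, dict] = {
    "P1": {
        "ops": [_op(_I)],
        # fully polar: origin free along every axis
        "origin_continuous": (True, True, True),
        "origin_discrete": ((0.0,), (0.0,), (0.0,)),
    },
    "P21": {
        # unique axis b: x,y,z / -x, y+1/2, -z
        "ops": [_op(_I), _op(((-1, 0, 0), (0, 1, 0), (0, 0, -1)), (0.0, 0.5, 0.0))],
        "origin_continuous": (False, True, False),
        "origin_discrete": ((0.0, 0.5), (0.0,), (0.0, 0.5)),
    },
    "P212121": {
        "ops": [
            _op(_I),
            _op(((-1, 0, 0), (0, -1, 0), (0, 0, 1)), (0.5, 0.0, 0.5)),
            _op(((-1, 0, 0), (0, 1, 0), (0, 0, -1)), (0.0, 0.5, 0.5)),
            _op(((1, 0, 0), (0, -1, 0), (0, 0, -1)), (0.5, 0.5, 0.0)),
        ],
        "origin_continuous": (False, False, False),
        "origin_discrete": ((0.0, 0.5), (0.0, 0.5), (0.0, 0.5)),
    },
}


@dataclass(frozen=True)
class SpaceGroup:
    """Space group restricted to the supported set (P1, P21, P212121).

    All three are Sohncke groups that map onto themselves under inversion,
    so the enantiomorph action is simply x -> -x with an unchanged symbol.
    """

    symbol: str
    ops: tuple[SymOp, ...] = field(init=False)

    def __post_init__(self) -> None:
        key = self.symbol.replace(" ", "")
        if key not in _SG_TABLE:
            raise ValueError(
                f"unsupported space group {self.symbol!r}; supported: {sorted(_SG_TABLE)}"
            )
        object.__setattr__(self, "symbol", key)
        object.__setattr__(self, "ops", tuple(_SG_TABLE[key]["ops"]))

    @property
    def n_ops(self) -> int:
        return len(self.ops)

    @property
    def origin_continuous(self) -> tuple[bool, bool, bool]:
        return _SG_TABLE[self.symbol]["origin_continuous"]

    @property
    def allowed_origin_shifts(self) -> list[np.ndarray]:
        """Discrete allowed origin shifts (continuous axes carry 0 here)."""
        ax = _SG_TABLE[self.symbol]["origin_discrete"]
        return [np.array(s, dtype=float) for s in itertools.product(*ax)]

    def enantiomorph_action(self, x: np.ndarray) -> np.ndarray:
        """Map site coordinates to the inverted hand: x -> -x (mod 1)."""
        return np.mod(-np.asarray(x, dtype=float), 1.0)

    # -- reflection classification ------------------------------------

    def is_centric(self, hkl: np.ndarray) -> np.ndarray:
        """Boolean per reflection: phase symmetry-restricted to two values."""
        h = np.atleast_2d(np.asarray(hkl, dtype=int))
        cen = np.zeros(len(h), dtype=bool)
        for op in self.ops:
            cen |= np.all(h @ op.R == -h, axis=1)
        return cen if np.asarray(hkl).ndim == 2 else cen[0]

    def centric_phase_restriction(self, hkl: np.ndarray) -> np.ndarray:
        """Allowed-phase axis for centric reflections, degrees in [0, 180).

        The restriction derives from the operator with h@R = -h:
        phi = 180 * h.t (mod 180); the two allowed phases are phi and
        phi + 180.  Non-centric rows get 0.0 (unused).
        """
        h = np.atleast_2d(np.asarray(hkl, dtype=int))
        phi = np.zeros(len(h), dtype=float)
        done = np.zeros(len(h), dtype=bool)
        for op in self.ops:
            sel = np.all(h @ op.R == -h, axis=1) & ~done
            if np.any(sel):
                phi[sel] = np.mod(180.0 * (h[sel] @ op.t), 180.0)
                done |= sel
        return phi if np.asarray(hkl).ndim == 2 else phi[0]

    def equivalent_hkl(self, hkl) -> set[tuple[int, int, int]]:
        """Orbit of hkl under the point group plus Friedel inversion."""
        h = np.asarray(hkl, dtype=int)
        out = set()
        for op in self.ops:
            hp = tuple(int(v) for v in h @ op.R)
            out.add(hp)
            out.add(tuple(-v for v in hp))
        return out


def d_spacing(cell: UnitCell, hkl) -> float | np.ndarray:
    """Resolution d = 1/|s| of reflection(s) hkl from the reciprocal metric.

    Symmetric in +-hkl.  Raises on the (0,0,0) triple.
    """
    h = np.asarray(hkl, dtype=float)
    single = h.ndim == 1
    h2 = np.atleast_2d(h)
    if np.any(np.all(h2 == 0, axis=1)):
        raise ValueError("(0,0,0) is not a valid reflection")
    gstar = cell.reciprocal_metric_tensor()
    s2 = np.einsum("ij,jk,ik->i", h2, gstar, h2)
    d = 1.0 / np.sqrt(s2)
    return float(d[0]) if single else d


def unique_reflections(cell: UnitCell, sg: SpaceGroup, d_min: float, d_max: float = float("inf")) -> np.ndarray:
    """Symmetry-unique Miller indices with d in [d_min, d_max].

    Canonical representative of each orbit (including Friedel mates) is the
    lexicographically greatest (h, k, l) tuple; output sorted by descending
    d then lexicographic hkl for deterministic downstream binning.
    """
    if d_min <= 0:
        raise ValueError("d_min must be positive")
    hmax = [int(np.floor(L / d_min)) + 1 for L in cell.lengths()]
    rng = [np.arange(-m, m + 1) for m in hmax]
    H = np.array(np.meshgrid(*rng, indexing="ij")).reshape(3, -1).T
    H = H[np.any(H != 0, axis=1)]
    gstar = cell.reciprocal_metric_tensor()
    s2 = np.einsum("ij,jk,ik->i", H, gstar, H)
    d = 1.0 / np.sqrt(s2)
    H = H[(d >= d_min) & (d <= d_max)]
    arr = canonical_hkl(sg, H, unique=True)
    dd = d_spacing(cell, arr)
    order = np.lexsort((arr[:, 2], arr[:, 1], arr[:, 0], -dd))
    return arr[order]


def canonical_hkl(sg: SpaceGroup, hkl: np.ndarray, unique: bool = False) -> np.ndarray:
    """Lexicographically-greatest orbit representative of each hkl under
    the point group plus Friedel inversion (vectorized)."""
    H = np.asarray(hkl, dtype=int).reshape(-1, 3)
    images = np.stack([H @ op.R for op in sg.ops] + [-(H @ op.R) for op in sg.ops])
    M = int(np.abs(images).max()) + 1
    base = 2 * M + 1
    keys = (images[..., 0] + M) * base * base + (images[..., 1] + M) * base + (images[..., 2] + M)
    best = np.argmax(keys, axis=0)
    rep = images[best, np.arange(len(H))]
    if unique:
        rep = np.unique(rep, axis=0)
    return rep


def epsilon_factor(sg: SpaceGroup, hkl: np.ndarray) -> np.ndarray:
    """Statistical multiplicity epsilon: number of point-group rotations
    fixing h (used for E-normalization)."""
    h = np.atleast_2d(np.asarray(hkl, dtype=int))
    eps = np.zeros(len(h), dtype=int)
    for op in self_rotations(sg):
        eps += np.all(h @ op == h, axis=1)
    return eps if np.asarray(hkl).ndim == 2 else eps[0]


def self_rotations(sg: SpaceGroup) -> list[np.ndarray]:
    return [op.R for op in sg.ops]


def frac_to_cart(cell: UnitCell, frac: np.ndarray) -> np.ndarray:
    return (cell.orthogonalization_matrix() @ np.asarray(frac, dtype=float).T).T


def min_image_distance(cell: UnitCell, fx: np.ndarray, fy: np.ndarray) -> float:
    """Distance in A between two fractional points under lattice translation."""
    d = np.asarray(fx, dtype=float) - np.asarray(fy, dtype=float)
    d -= np.round(d)
    # check neighbouring images to be safe for very oblique cells
    best = np.inf
    for shift in itertools.product((-1, 0, 1), repeat=3):
        v = frac_to_cart(cell, d + np.array(shift))
        best = min(best, float(np.linalg.norm(v)))
    return best
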
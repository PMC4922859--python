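"""Linear stability analysis of reaction-diffusion systems.

The linearised dynamics of a reaction-diffusion system around its
homogeneous steady state decompose into independent spatial modes with
wave number ``q``; mode ``q`` evolves under the matrix ``J - q^2 D``,
where ``J`` is the reaction Jacobian and ``D`` the diagonal matrix of
diffusion coefficients.  A diffusion-driven (Turing) instability requires
the steady state to be stable for the homogeneous mode (``q = 0``) but
unstable for some ``q > 0``.

This module provides the characteristic polynomial of ``J - q^2 D``, the
Routh-Hurwitz stability test on its coefficients, the dispersion relation
``max Re lambda(q^2)`` with its analytic ``q -> infinity`` limit (the
spectral abscissa of the non-diffusible sub-block), and the Turing
decision itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RDSystem",
    "CharPoly",
    "DispersionRelation",
    "StabilityReport",
    "char_poly_coeffs",
    "routh_hurwitz_stable",
    "spectral_abscissa",
    "dispersion",
    "is_turing_unstable",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class RDSystem:
    """A concrete reaction-diffusion system: rates plus diffusion.

    Parameters
    ----------
    J : (N, N) array
        First-order kinetic rates; ``J[i, j]`` is the influence of node
        ``j`` on node ``i`` (positive = activation, negative = inhibition).
    D : (N,) array
        Per-node diffusion coefficients; exactly the non-diffusible nodes
        have ``d_i = 0``.
    topology : optional
        The signed topology this system instantiates (``screen.Topology``).
        When given, the sign and support of ``J`` are validated against it.
    """

    J: np.ndarray
    D: np.ndarray
    topology: object | None = None

    def __post_init__(self):
        self.J = np.asarray(self.J, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        if self.J.ndim != 2 or self.J.shape[0] != self.J.shape[1]:
            raise ValueError(f"J must be square, got shape {self.J.shape}")
        if self.D.shape != (self.J.shape[0],):
            raise ValueError("D must be a length-N vector of diffusion coefficients")
        if (self.D < 0).any():
            raise ValueError("diffusion coefficients must be nonnegative")
        if self.topology is not None:
            support = {tuple(e) for e in self.topology.network.edges}
            nz = {(i, j) for i, j in zip(*np.nonzero(self.J))}
            if not nz <= support:
                raise ValueError("J has entries outside the topology's edge support")
            for (i, j), sign in self.topology.signs.items():
                v = self.J[i, j]
                if v != 0 and np.sign(v) != sign:
                    raise ValueError(f"J[{i},{j}]={v} contradicts topology sign {sign:+d}")

    @property
    def n_nodes(self) -> int:
        return self.J.shape[0]

    @property
    def diffusible_mask(self) -> np.ndarray:
        return self.D > 0


@dataclass(frozen=True)
class CharPoly:
    """Coefficients ``a_1 .. a_N`` of ``lambda^N + a_1 lambda^(N-1) + ... + a_N``,
    evaluated at a particular ``q^2``."""

    coeffs: tuple[float, ...]
    q2: float = 0.0

    @property
    def degree(self) -> int:
        return len(self.coeffs)

    def as_numpy(self) -> np.ndarray:
        """Full coefficient vector ``[1, a_1, ..., a_N]`` for numpy.roots."""
        return np.concatenate([[1.0], np.asarray(self.coeffs)])

    def roots(self) -> np.ndarray:
        return np.roots(self.as_numpy())


@dataclass
class DispersionRelation:
    """``max Re lambda`` of ``J - q^2 D`` sampled over a ``q^2`` grid.

    ``q_star`` is the growth-maximising wave number squared; it is
    ``numpy.inf`` when the supremum is attained only in the
    ``q -> infinity`` limit, whose value is the spectral abscissa of the
    non-diffusible sub-block (``-inf`` for an empty block).
    """

    q2_grid: np.ndarray
    max_re_lambda: np.ndarray
    is_real: np.ndarray
    q_star: float
    max_growth: float
    eigvec_star: np.ndarray
    limit_at_infinity: float

    def to_records(self) -> list[dict]:
        return [
            {"q2": float(q), "max_re_lambda": float(m), "dominant_root_real": bool(r)}
            for q, m, r in zip(self.q2_grid, self.max_re_lambda, self.is_real)
        ]


@dataclass
class StabilityReport:
    """Outcome of the Turing decision for one parameterised system."""

    stable_at_q0: bool
    turing_unstable: bool
    q_star: float
    oscillatory: bool
    max_growth: float
    dispersion: DispersionRelation | None = None
    char_polys: list[CharPoly] = field(default_factory=list)

    def __post_init__(self):
        # diffusion-driven only, by construction
        if self.turing_unstable and not self.stable_at_q0:
            raise ValueError("turing_unstable requires stability of the homogeneous mode")


# ---------------------------------------------------------------------------
# characteristic polynomial
# ---------------------------------------------------------------------------

def _fl_coeffs(M: np.ndarray) -> np.ndarray:
    """Characteristic polynomial coefficients a_1..a_N of det(lambda I - M)
    via the Faddeev-LeVerrier recursion (exact in rational arithmetic,
    numerically adequate for the tiny well-scaled matrices used here)."""
    n = M.shape[0]
    a = np.empty(n)
    Mk = M.copy()
    a[0] = -np.trace(Mk)
    I = np.eye(n)
    for k in range(1, n):
        Mk = M @ (Mk + a[k - 1] * I)
        a[k] = -np.trace(Mk) / (k + 1)
    return a


def char_poly_coeffs(J: np.ndarray, D: np.ndarray | None = None, q2: float = 0.0) -> CharPoly:
    """Coefficients of ``det(lambda I - (J - q^2 diag(D)))`` expanded in lambda.

    Equivalently, ``a_m`` equals ``(-1)^m`` times the sum of the order-m
    principal minors of ``J - q^2 diag(D)``.
    """
    J = np.asarray(J, dtype=float)
    if J.ndim != 2 or J.shape[0] != J.shape[1]:
        raise ValueError(f"J must be square, got shape {J.shape}")
    M = J.copy()
    if D is not None:
        D = np.asarray(D, dtype=float)
        if D.ndim == 0:
            D = np.full(J.shape[0], float(D))
        if D.shape != (J.shape[0],):
            raise ValueError("D must be scalar or a length-N vector")
        M = M - q2 * np.diag(D)
    return CharPoly(tuple(_fl_coeffs(M)), q2=float(q2))


# ---------------------------------------------------------------------------
# Routh-Hurwitz
# ---------------------------------------------------------------------------

def _routh_array_stable(coeffs: np.ndarray) -> bool:
    """Full Routh array for arbitrary degree; zero pivots are treated as
    failures (marginal systems count as not strictly stable)."""
    c = np.concatenate([[1.0], coeffs])
    n = len(c) - 1
    rows = [c[0::2].copy(), c[1::2].copy()]
    width = len(rows[0])
    rows[1] = np.pad(rows[1], (0, width - len(rows[1])))
    for _ in range(n - 1):
        top, bot = rows[-2], rows[-1]
        if bot[0] == 0:
            return False
        new = np.zeros(width)
        for j in range(width - 1):
            new[j] = (bot[0] * top[j + 1] - top[0] * bot[j + 1]) / bot[0]
        rows.append(new)
    first_col = np.array([r[0] for r in rows])
    return bool((first_col > 0).all())


def routh_hurwitz_stable(coeffs: CharPoly | tuple | list | np.ndarray) -> bool:
    """True iff all roots of the monic polynomial have negative real parts.

    Degrees 2-4 use the explicit criteria; degree 5 falls back to the full
    Routh array.  Higher degrees raise, mirroring the Abel-Ruffini limit
    of the screening method.
    """
    if isinstance(coeffs, CharPoly):
        a = np.asarray(coeffs.coeffs, dtype=float)
    else:
        a = np.asarray(coeffs, dtype=float)
    n = len(a)
    if n == 2:
        a1, a2 = a
        return bool(a1 > 0 and a2 > 0)
    if n == 3:
        a1, a2, a3 = a
        return bool(a1 > 0 and a3 > 0 and a1 * a2 > a3)
    if n == 4:
        a1, a2, a3, a4 = a
        return bool(
            a1 > 0 and a3 > 0 and a4 > 0 and a1 * a2 * a3 > a3 * a3 + a1 * a1 * a4
        )
    if n == 5:
        return _routh_array_stable(a)
    raise ValueError(f"unsupported polynomial degree {n}; supported degrees are 2..5")


def spectral_abscissa(M: np.ndarray) -> float:
    """Largest real part of the eigenvalues; ``-inf`` for an empty matrix."""
    M = np.atleast_2d(np.asarray(M, dtype=float))
    if M.size == 0:
        return -np.inf
    return float(np.linalg.eigvals(M).real.max())


# ---------------------------------------------------------------------------
# dispersion relation
# ---------------------------------------------------------------------------

_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


def _max_re(J, D, q2):
    ev = np.linalg.eigvals(J - q2 * np.diag(D))
    i = int(np.argmax(ev.real))
    return ev.real[i], ev, i


def dispersion(
    J: np.ndarray,
    D: np.ndarray,
    q2_min: float = 1e-3,
    q2_max: float = 1e3,
    n_grid: int = 64,
    refine: bool = True,
    imag_tol: float = 1e-9,
) -> DispersionRelation:
    """Evaluate ``max Re lambda(q^2)`` on a logarithmic grid and refine.

    The analytic ``q -> infinity`` limit is computed as the spectral
    abscissa of the sub-Jacobian of the non-diffusible nodes: diffusive
    modes decay like ``-q^2 d_i`` while the immobile block is untouched by
    diffusion.  Bounded grids alone would miss instabilities that peak in
    that limit, so the limit participates in locating ``q_star``.
    """
    J = np.asarray(J, dtype=float)
    D = np.asarray(D, dtype=float)
    n = J.shape[0]
    grid = np.concatenate([[0.0], np.logspace(np.log10(q2_min), np.log10(q2_max), n_grid)])
    vals = np.empty_like(grid)
    real_flags = np.empty(len(grid), dtype=bool)
    for idx, q2 in enumerate(grid):
        mr, ev, i = _max_re(J, D, q2)
        vals[idx] = mr
        real_flags[idx] = abs(ev[i].imag) <= imag_tol * max(1.0, abs(ev[i].real))

    immobile = np.flatnonzero(D == 0)
    limit = spectral_abscissa(J[np.ix_(immobile, immobile)]) if len(immobile) else -np.inf

    best = int(np.argmax(vals))
    q_star = grid[best]
    max_growth = vals[best]

    if refine and 0 < best < len(grid) - 1:
        lo, hi = grid[best - 1], grid[best + 1]
        f = lambda x: _max_re(J, D, x)[0]
        a, b = lo, hi
        x1 = b - _GOLDEN * (b - a)
        x2 = a + _GOLDEN * (b - a)
        f1, f2 = f(x1), f(x2)
        for _ in range(48):
            if f1 >= f2:
                b, x2, f2 = x2, x1, f1
                x1 = b - _GOLDEN * (b - a)
                f1 = f(x1)
            else:
                a, x1, f1 = x1, x2, f2
                x2 = a + _GOLDEN * (b - a)
                f2 = f(x2)
        q_ref = (a + b) / 2.0
        v_ref = f(q_ref)
        if v_ref > max_growth:
            q_star, max_growth = q_ref, v_ref

    if limit > max_growth:
        q_star = np.inf
        max_growth = limit
        # eigenvector at a large but finite q^2 as a practical stand-in
        _, ev, i = _max_re(J, D, q2_max * 1e3)
        eigvec = np.linalg.eig(J - q2_max * 1e3 * np.diag(D))[1][:, i]
    else:
        _, evals, i = _max_re(J, D, q_star)
        eigvec = np.linalg.eig(J - q_star * np.diag(D))[1][:, i]

    return DispersionRelation(
        q2_grid=grid,
        max_re_lambda=vals,
        is_real=real_flags,
        q_star=float(q_star),
        max_growth=float(max_growth),
        eigvec_star=eigvec,
        limit_at_infinity=float(limit),
    )


# ---------------------------------------------------------------------------
# the Turing decision
# ---------------------------------------------------------------------------

def is_turing_unstable(
    sys: RDSystem,
    eps: float = 1e-9,
    stationary_only: bool = False,
    require_wavelength_selection: bool = False,
    **disp_kwargs,
) -> StabilityReport:
    """Decide diffusion-driven instability for a parameterised system.

    The default follows the screening pipeline's stated criterion: the
    homogeneous mode must be strictly stable (Routh-Hurwitz at
    ``q^2 = 0``) and some mode ``q > 0`` - the ``q -> infinity`` limit
    included - must grow, complex dominant roots accepted.  The
    ``oscillatory`` flag records whether the dominant root at ``q_star``
    has a nonzero imaginary part so downstream consumers can filter for
    stationary patterns.

    Options
    -------
    stationary_only : bool
        Require the growing mode to be non-oscillatory.
    require_wavelength_selection : bool
        Additionally require the growth maximum at a finite wave number
        (spectral abscissa of the immobile block nonpositive); this is the
        catalog convention used by the screen module.
    """
    mask = sys.diffusible_mask
    if (sys.D[mask] <= 0).any():
        raise ValueError("all diffusible nodes need d_i > 0 for the Turing decision")
    scale = np.abs(sys.J).max()
    tol = eps * (scale if scale > 0 else 1.0)

    cp0 = char_poly_coeffs(sys.J)
    stable0 = routh_hurwitz_stable(cp0)
    disp = dispersion(sys.J, sys.D, **disp_kwargs)

    grows = disp.max_growth > tol
    oscillatory = False
    if grows and np.isfinite(disp.q_star):
        ev = np.linalg.eigvals(sys.J - disp.q_star * np.diag(sys.D))
        dom = ev[np.argmax(ev.real)]
        oscillatory = abs(dom.imag) > 1e-9 * max(1.0, abs(dom.real))

    turing = stable0 and grows
    if turing and stationary_only and oscillatory:
        turing = False
    if turing and require_wavelength_selection and disp.limit_at_infinity > tol:
        turing = False

    samples = [cp0] + [
        char_poly_coeffs(sys.J, sys.D, q2)
        for q2 in np.logspace(-2, 2, 5)
    ]
    return StabilityReport(
        stable_at_q0=bool(stable0),
        turing_unstable=bool(turing),
        q_star=disp.q_star if turing else (0.0 if not grows else disp.q_star),
        oscillatory=oscillatory,
        max_growth=disp.max_growth,
        dispersion=disp,
        char_polys=samples,
    )
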
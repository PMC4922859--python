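"""Vectorised Monte-Carlo engine behind the screening pipeline.

Everything here operates on batches of Jacobians assembled from a signed
edge support.  The public surface of the package (module ``screen``)
wraps these helpers; they are deliberately free of domain objects so the
hot loops stay plain numpy.

Reproducibility contract: every topology draws from its own RNG stream
(derived from the run seed plus stable indices) in fixed-size chunks, so
the decision for one topology never depends on which other topologies
are still undecided, and survivors at budget ``B`` are a subset of
survivors at any larger budget.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

Edge = tuple[int, int]

_ZTOL = 1e-13  # absolute tolerance for structurally-zero coefficients
_DIP_TOL = 1e-12


# ---------------------------------------------------------------------------
# batched characteristic polynomial and stability masks
# ---------------------------------------------------------------------------

def char_coeffs_batch(M: np.ndarray) -> np.ndarray:
    """Coefficients a_1..a_N for a (B, N, N) batch (Faddeev-LeVerrier)."""
    b, n, _ = M.shape
    a = np.empty((b, n))
    I = np.eye(n)[None]
    Mk = M.copy()
    a[:, 0] = -np.trace(Mk, axis1=1, axis2=2)
    for k in range(1, n):
        Mk = M @ (Mk + a[:, k - 1, None, None] * I)
        a[:, k] = -np.trace(Mk, axis1=1, axis2=2) / (k + 1)
    return a


_POS_TOL = 1e-12  # floor separating genuine positivity from round-off on
                  # structurally singular Jacobians (whose trailing
                  # coefficients are zero up to ~1e-17 noise)


def rh_strict_batch(a: np.ndarray) -> np.ndarray:
    """Strict Routh-Hurwitz mask for coefficient batches of degree 2..5."""
    n = a.shape[1]
    t = _POS_TOL
    if n == 2:
        return (a[:, 0] > t) & (a[:, 1] > t)
    if n == 3:
        a1, a2, a3 = a[:, 0], a[:, 1], a[:, 2]
        return (a1 > t) & (a3 > t) & (a1 * a2 > a3)
    if n == 4:
        a1, a2, a3, a4 = a.T
        return (a1 > t) & (a3 > t) & (a4 > t) & (a1 * a2 * a3 > a3 * a3 + a1 * a1 * a4)
    if n == 5:
        return _routh_batch(a) & (np.abs(a) > t).all(axis=1)
    raise ValueError(f"unsupported degree {n}")


def _routh_batch(a: np.ndarray) -> np.ndarray:
    """Vectorised Routh array; zero pivots classified unstable."""
    b = a.shape[0]
    c = np.concatenate([np.ones((b, 1)), a], axis=1)
    n = c.shape[1] - 1
    width = (n + 2) // 2
    top = np.zeros((b, width))
    bot = np.zeros((b, width))
    top[:, : len(range(0, n + 1, 2))] = c[:, 0::2]
    bot[:, : len(range(1, n + 1, 2))] = c[:, 1::2]
    ok = np.ones(b, dtype=bool)
    first_cols = [top[:, 0], bot[:, 0]]
    for _ in range(n - 1):
        pivot = bot[:, 0]
        ok &= pivot != 0
        safe = np.where(pivot == 0, 1.0, pivot)
        new = np.zeros_like(top)
        new[:, :-1] = (safe[:, None] * top[:, 1:] - top[:, 0:1] * bot[:, 1:]) / safe[:, None]
        top, bot = bot, new
        first_cols.append(bot[:, 0])
    stacked = np.stack(first_cols, axis=1)
    return ok & (stacked > 0).all(axis=1)


def _strict_reduced(a: np.ndarray, deg: int) -> np.ndarray:
    """Strict stability of the leading monic factor of degree ``deg``."""
    if deg == 1:
        return a[:, 0] > 0
    return rh_strict_batch(a[:, :deg])


def semistable_batch(a: np.ndarray) -> np.ndarray:
    """Strictly stable, or structurally singular with a stable reduced
    factor (trailing characteristic coefficients identically zero).

    A Jacobian whose trailing coefficients vanish *structurally* (e.g. two
    nodes driven by the same single regulator) carries exact zero
    eigenvalues; the steady state is then marginally stable when the
    remaining factor satisfies Routh-Hurwitz.  Such semistable base states
    are admitted by the screen.
    """
    n = a.shape[1]
    out = rh_strict_batch(a)
    for t in range(1, n - 1):
        zeros = (np.abs(a[:, n - t:]) < _ZTOL).all(axis=1)
        out |= zeros & _strict_reduced(a, n - t)
    return out


# ---------------------------------------------------------------------------
# diffusion structure
# ---------------------------------------------------------------------------

def block_ok_batch(J: np.ndarray, diffusible: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Spectral abscissa of the non-diffusible sub-block <= tol.

    This is the wavelength-selection condition: as ``q -> infinity`` the
    diffusive modes decay and the dominant growth tends to the immobile
    block's abscissa, so a positive abscissa would put the growth maximum
    at infinite wave number.
    """
    idx = np.flatnonzero(~diffusible)
    s = len(idx)
    if s == 0:
        return np.ones(J.shape[0], dtype=bool)
    B = J[np.ix_(range(J.shape[0]), idx, idx)]
    if s == 1:
        return B[:, 0, 0] <= tol
    if s == 2:
        tr = B[:, 0, 0] + B[:, 1, 1]
        det = B[:, 0, 0] * B[:, 1, 1] - B[:, 0, 1] * B[:, 1, 0]
        return (tr <= tol) & (det >= -tol)
    ev = np.linalg.eigvals(B)
    return ev.real.max(axis=1) <= tol


def _submatrix_dets(J: np.ndarray, drop: tuple[int, ...]) -> np.ndarray:
    keep = [i for i in range(J.shape[1]) if i not in drop]
    if not keep:
        return np.ones(J.shape[0])
    sub = J[np.ix_(range(J.shape[0]), keep, keep)]
    if len(keep) == 1:
        return sub[:, 0, 0]
    if len(keep) == 2:
        return sub[:, 0, 0] * sub[:, 1, 1] - sub[:, 0, 1] * sub[:, 1, 0]
    return np.linalg.det(sub)


def an_poly_coeffs(J: np.ndarray, diffusible: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Coefficients (in x = q^2) of a_N(x) = (-1)^N det(J - x diag(d)).

    ``d`` is a (B, m) batch of diffusion coefficients for the diffusible
    nodes (in index order).  Returns (B, m+1) coefficients, constant term
    first.  Expansion over subsets S of diffusible nodes:
    det(J - x diag(d)) = sum_S (-x)^{|S|} prod_{i in S} d_i * det(J minus S).
    """
    n = J.shape[1]
    diff_idx = tuple(np.flatnonzero(diffusible))
    m = len(diff_idx)
    sgn_n = (-1.0) ** n
    coeffs = np.zeros((J.shape[0], m + 1))
    for r in range(m + 1):
        for S in itertools.combinations(range(m), r):
            drop = tuple(diff_idx[i] for i in S)
            term = _submatrix_dets(J, drop)
            if S:
                term = term * np.prod(d[:, list(S)], axis=1)
            coeffs[:, r] += sgn_n * (-1.0) ** r * term
    return coeffs


def dip_mask(coeffs: np.ndarray, grid: np.ndarray, tol: float = _DIP_TOL) -> np.ndarray:
    """True where a_N(x) < -tol for some x > 0: a real positive root of
    the characteristic polynomial exists at that wave number.

    Evaluated on the grid; for the common two-diffusible-node case the
    polynomial is a quadratic in x whose interior minimum is also checked
    exactly, so narrow instability windows between grid points are not
    missed.
    """
    powers = grid[None, :] ** np.arange(coeffs.shape[1])[:, None]  # (m+1, G)
    vals = coeffs @ powers
    out = (vals < -tol).any(axis=1)
    if coeffs.shape[1] == 3:
        c0, c1, c2 = coeffs[:, 0], coeffs[:, 1], coeffs[:, 2]
        with np.errstate(divide="ignore", invalid="ignore"):
            xv = -c1 / (2.0 * c2)
            vv = c0 + c1 * xv + c2 * xv * xv
        interior = (c2 > 0) & (xv > 0) & np.isfinite(xv)
        out |= interior & (vv < -tol)
    return out


# ---------------------------------------------------------------------------
# topology sampling
# ---------------------------------------------------------------------------

@dataclass
class TopologySpec:
    """Signed edge support plus optional fixed rate magnitudes."""

    n_nodes: int
    diffusible: np.ndarray          # (N,) bool
    edges: tuple[Edge, ...]         # sorted, row-major
    signs: np.ndarray               # (k,) entries +-1
    fixed_values: np.ndarray        # (k,) float, nan = free magnitude

    def __post_init__(self):
        self.diffusible = np.asarray(self.diffusible, dtype=bool)
        self.signs = np.asarray(self.signs, dtype=float)
        self.fixed_values = np.asarray(self.fixed_values, dtype=float)
        self._rows = np.array([e[0] for e in self.edges])
        self._cols = np.array([e[1] for e in self.edges])
        fixed = ~np.isnan(self.fixed_values)
        bad = fixed & (np.sign(self.fixed_values) != self.signs)
        if bad.any():
            raise ValueError("fixed rate values must match the topology's edge signs")

    @property
    def n_diffusible(self) -> int:
        return int(self.diffusible.sum())

    def assemble(self, mags: np.ndarray) -> np.ndarray:
        """Jacobian batch from (B, k) magnitudes (fixed cells overridden)."""
        vals = self.signs[None, :] * mags
        fixed = ~np.isnan(self.fixed_values)
        if fixed.any():
            vals = vals.copy()
            vals[:, fixed] = self.fixed_values[fixed]
        J = np.zeros((mags.shape[0], self.n_nodes, self.n_nodes))
        J[:, self._rows, self._cols] = vals
        return J


@dataclass
class SamplerOptions:
    """Knobs of the existence sampler.

    budget
        Parameter draws per topology per decision (default 20,000).
    rate_high
        Upper magnitude bound; rates live in the box (-0.5, 0.5), so free
        magnitudes are uniform on (0, 0.5].
    stability
        "semistable" (default) or "strict".
    wavelength_selection
        Require the immobile block's abscissa <= tol (finite q*).
    """

    budget: int = 20000
    chunk: int = 4000
    rate_high: float = 0.5
    diff_high: float = 1.0
    stability: str = "strict"
    wavelength_selection: bool = True
    q2_grid: np.ndarray = field(default_factory=lambda: np.logspace(-3, 3, 32))
    block_tol: float = 1e-12
    probe_ratios: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0, 100.0)

    def stability_mask(self, coeffs: np.ndarray) -> np.ndarray:
        if self.stability == "strict":
            return rh_strict_batch(coeffs)
        if self.stability == "semistable":
            return semistable_batch(coeffs)
        raise ValueError(f"unknown stability mode {self.stability!r}")


@dataclass
class Witness:
    """A replayable parameter set certifying a decision."""

    J: np.ndarray
    D: np.ndarray
    seed_info: tuple
    strict_stable: bool = True


def topology_rng(seed: int, *indices: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(int(i) for i in indices)))


def _draw_diffusion(rng, regime, n_draws: int, m: int, diff_high: float) -> np.ndarray:
    kind = regime[0]
    if kind == "free":
        return rng.uniform(0.0, diff_high, size=(n_draws, m)).clip(min=1e-12)
    if kind == "equal":
        base = rng.uniform(0.0, diff_high, size=n_draws).clip(min=1e-12)
        return np.repeat(base[:, None], m, axis=1)
    if kind == "ratio":
        if m != 2:
            raise ValueError("ratio regime requires exactly two diffusible nodes")
        r = float(regime[1])
        base = np.full(n_draws, 0.5 * min(1.0, 1.0 / r) * diff_high)
        return np.stack([base, base * r], axis=1)
    if kind == "fixed":
        vec = np.asarray(regime[1], dtype=float)
        if vec.shape != (m,):
            raise ValueError("fixed regime needs one value per diffusible node")
        return np.repeat(vec[None, :], n_draws, axis=0)
    raise ValueError(f"unknown diffusion regime {kind!r}")


def _turing_masks(spec: TopologySpec, J: np.ndarray, d: np.ndarray, opts: SamplerOptions):
    """(base_stable, strict_stable, turing) masks for a (J, d) batch."""
    coeffs = char_coeffs_batch(J)
    strict = rh_strict_batch(coeffs)
    base = opts.stability_mask(coeffs)
    ok = base.copy()
    if opts.wavelength_selection:
        ok &= block_ok_batch(J, spec.diffusible, opts.block_tol)
    dip = np.zeros(J.shape[0], dtype=bool)
    if ok.any():
        an = an_poly_coeffs(J[ok], spec.diffusible, d[ok])
        dip_sub = dip_mask(an, opts.q2_grid)
        dip[np.flatnonzero(ok)[dip_sub]] = True
    if not opts.wavelength_selection:
        # permissive criterion: an unstable immobile block certifies
        # growth in the q -> infinity limit for every diffusion choice
        unstable_block = ~block_ok_batch(J, spec.diffusible, opts.block_tol)
        dip |= base & unstable_block
    return base, strict, base & dip


def find_stable_witness(spec: TopologySpec, opts: SamplerOptions, rng) -> Witness | None:
    """First sampled rate set with an admissible (semi)stable steady state."""
    k = len(spec.edges)
    drawn = 0
    while drawn < opts.budget:
        n = min(opts.chunk, opts.budget - drawn)
        mags = rng.uniform(0.0, opts.rate_high, size=(n, k)).clip(min=1e-12)
        drawn += n
        J = spec.assemble(mags)
        coeffs = char_coeffs_batch(J)
        mask = opts.stability_mask(coeffs)
        if mask.any():
            i = int(np.argmax(mask))
            return Witness(J[i], np.zeros(spec.n_nodes), ("stable",),
                           strict_stable=bool(rh_strict_batch(coeffs[i:i + 1])[0]))
    return None


def find_turing_witness(
    spec: TopologySpec,
    regime,
    opts: SamplerOptions,
    rng,
    phase_filter=None,
    phase_tries: int = 8,
) -> Witness | None:
    """First sampled (rates, diffusion) passing stability + instability.

    ``phase_filter``, when given, receives the candidate ``Witness`` and
    may veto it (used for in-phase / out-of-phase screen constraints).
    """
    k = len(spec.edges)
    m = spec.n_diffusible
    diff_idx = np.flatnonzero(spec.diffusible)
    drawn = 0
    while drawn < opts.budget:
        n = min(opts.chunk, opts.budget - drawn)
        mags = rng.uniform(0.0, opts.rate_high, size=(n, k)).clip(min=1e-12)
        d = _draw_diffusion(rng, regime, n, m, opts.diff_high)
        drawn += n
        J = spec.assemble(mags)
        _, strict, turing = _turing_masks(spec, J, d, opts)
        if not turing.any():
            continue
        hits = np.flatnonzero(turing)
        for i in hits[:phase_tries] if phase_filter else hits[:1]:
            D = np.zeros(spec.n_nodes)
            D[diff_idx] = d[i]
            w = Witness(J[i], D, ("turing", regime[0]), strict_stable=bool(strict[i]))
            if phase_filter is None or phase_filter(w):
                return w
    return None


def verify_witness(spec: TopologySpec, w: Witness, opts: SamplerOptions) -> bool:
    """Replay a recorded witness through the same decision masks."""
    d = w.D[np.flatnonzero(spec.diffusible)][None, :]
    _, _, turing = _turing_masks(spec, w.J[None], d, opts)
    return bool(turing[0])


# ---------------------------------------------------------------------------
# classification helpers
# ---------------------------------------------------------------------------

def _dip_at_ratios(spec: TopologySpec, J: np.ndarray, ratios, opts: SamplerOptions) -> np.ndarray:
    """For each Jacobian in the batch: does a stationary dip exist at
    every diffusion ratio in ``ratios`` (same rates throughout)?"""
    m = spec.n_diffusible
    out = np.ones(J.shape[0], dtype=bool)
    for r in ratios:
        if m == 2:
            base = 0.5 * min(1.0, 1.0 / r) * opts.diff_high
            d = np.tile([base, base * r], (J.shape[0], 1))
        else:
            # general m: one node scaled by r against the rest
            d = np.full((J.shape[0], m), 0.5 * min(1.0, 1.0 / r) * opts.diff_high)
            d[:, -1] *= r
        an = an_poly_coeffs(J, spec.diffusible, d)
        out &= dip_mask(an, opts.q2_grid)
        if not out.any():
            break
    return out


def classification_flags(spec: TopologySpec, opts: SamplerOptions, rng) -> dict:
    """Diffusivity-requirement flags for one topology.

    equal_capable
        some sampled admissible rate set is unstable at equal diffusivities
        (Type II requirement: "allows for equal diffusivity");
    universal_capable
        some *strictly* stable rate set is unstable at every probed
        diffusion ratio simultaneously (Type III: the pattern-forming
        conditions leave all positive diffusion coefficients admissible).
    """
    k = len(spec.edges)
    equal = False
    universal = False
    drawn = 0
    while drawn < opts.budget and not (equal and universal):
        n = min(opts.chunk, opts.budget - drawn)
        mags = rng.uniform(0.0, opts.rate_high, size=(n, k)).clip(min=1e-12)
        drawn += n
        J = spec.assemble(mags)
        coeffs = char_coeffs_batch(J)
        strict = rh_strict_batch(coeffs)
        base = opts.stability_mask(coeffs)
        if opts.wavelength_selection:
            base &= block_ok_batch(J, spec.diffusible, opts.block_tol)
            strict = strict & base
        if not base.any():
            continue
        if not equal:
            Jb = J[base]
            d_eq = np.full((Jb.shape[0], spec.n_diffusible), 0.5 * opts.diff_high)
            an = an_poly_coeffs(Jb, spec.diffusible, d_eq)
            if dip_mask(an, opts.q2_grid).any():
                equal = True
        if not universal and strict.any():
            if _dip_at_ratios(spec, J[strict], opts.probe_ratios, opts).any():
                universal = True
    return {"equal_capable": equal, "universal_capable": universal}


def ratio_feasible(spec: TopologySpec, ratio: float, opts: SamplerOptions, rng) -> bool:
    """Existence of an admissible rate set patterning at a fixed ratio."""
    w = find_turing_witness(spec, ("ratio", ratio), opts, rng)
    return w is not None


# ---------------------------------------------------------------------------
# robustness
# ---------------------------------------------------------------------------

def robustness_fraction(
    spec: TopologySpec,
    regime,
    n_samples: int,
    opts: SamplerOptions,
    rng,
) -> tuple[int, int]:
    """Hits and trials for the Turing-space volume estimate.

    Rates are drawn uniformly from the box (-0.5, 0.5) restricted to the
    topology's signs, diffusion uniformly from (0, 1) under the regime;
    a hit passes homogeneous stability plus the instability test.
    """
    k = len(spec.edges)
    m = spec.n_diffusible
    hits = 0
    done = 0
    while done < n_samples:
        n = min(opts.chunk, n_samples - done)
        mags = rng.uniform(0.0, opts.rate_high, size=(n, k)).clip(min=1e-12)
        d = _draw_diffusion(rng, regime, n, m, opts.diff_high)
        done += n
        J = spec.assemble(mags)
        _, _, turing = _turing_masks(spec, J, d, opts)
        hits += int(turing.sum())
    return hits, done
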
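"""The high-throughput screen: pipeline steps 1-6 with constraints.

The pipeline enumerates candidate networks (step 1), keeps strongly
connected ones (step 2), deduplicates isomorphic networks (step 3),
keeps networks with at least one sign assignment admitting a stable
homogeneous steady state (step 4), keeps those where diffusion
destabilises some spatial mode (step 5), and finally maps surviving sign
assignments to the in-phase / out-of-phase patterns they produce and to
their diffusivity requirements (step 6):

* Type I   - patterning requires unequal diffusion coefficients,
* Type II  - patterning is possible with equal diffusivities,
* Type III - one rate set patterns at every probed diffusion ratio.

Step 5 uses the catalog convention: the instability must be stationary
(a real positive root, i.e. ``a_N(q^2) < 0`` somewhere) and the growth
maximum must sit at a finite wave number (the immobile sub-block is not
itself unstable), so every hit selects a wavelength.  The permissive
variant of the criterion - any eigenvalue with positive real part,
including the ``q -> infinity`` capacitor limit - is available through
``ScreenOptions(wavelength_selection=False)``.

Surviving sign assignments are reported both raw and grouped by the
phase pattern they realise; the published step counts tally one topology
per distinct phase pattern per network.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _engine as eng
from .lsa import RDSystem, dispersion
from .netspace import (
    Edge,
    NetworkGraph,
    NodeSpec,
    canonical_key,
    class_preserving_permutations,
    count_networks,
    dedup_networks,
    enumerate_networks,
    passes_connectivity_filter,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Topology",
    "ConstraintSet",
    "DiffusionRegime",
    "ScreenOptions",
    "RobustnessOptions",
    "RobustnessEstimate",
    "SurvivingTopology",
    "CatalogEntry",
    "StepTable",
    "ScreenResult",
    "enumerate_topologies",
    "topology_is_stable",
    "topology_turing_capable",
    "phase_pattern",
    "classify_network",
    "robustness",
    "min_diffusion_ratio",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Topology:
    """A network plus one activation/inhibition sign per edge."""

    network: NetworkGraph
    signs: dict  # Edge -> +-1

    def __post_init__(self):
        if set(self.signs) != set(self.network.edges):
            raise ValueError("signs must cover exactly the network's edges")
        if any(s not in (+1, -1) for s in self.signs.values()):
            raise ValueError("edge signs must be +1 or -1")

    def sign_vector(self) -> np.ndarray:
        return np.array([self.signs[e] for e in self.network.sorted_edges()], dtype=float)

    def sign_bits(self) -> str:
        return "".join("1" if self.signs[e] > 0 else "0" for e in self.network.sorted_edges())

    def sign_matrix(self) -> np.ndarray:
        m = np.zeros((self.network.n_nodes,) * 2)
        for e, s in self.signs.items():
            m[e] = s
        return m


def _resolve_node(ref, nodes: tuple[NodeSpec, ...]) -> int:
    if isinstance(ref, (int, np.integer)):
        if not 0 <= ref < len(nodes):
            raise ValueError(f"node index {ref} out of range")
        return int(ref)
    for n in nodes:
        if n.label == ref:
            return n.index
    raise ValueError(f"unknown node reference {ref!r}")


@dataclass
class ConstraintSet:
    """Experimental knowledge injected into a screen.

    All edge containers use ``(target, source)`` cells.  ``zero_edges``
    are cells forced to zero (excluded from every candidate network);
    ``forced_edges`` must appear in every candidate.  ``sign_constraints``
    fix activation/inhibition, ``value_constraints`` fix the full signed
    rate.  ``fixed_diffusion`` pins diffusion coefficients per node and
    ``fixed_ratio`` pins the ratio between the two diffusible nodes.
    Phase requirements select topologies by the spatial pattern they
    produce: every group in ``in_phase`` must share a sign, every pair in
    ``out_of_phase`` must differ.
    """

    forced_edges: frozenset = frozenset()
    zero_edges: frozenset = frozenset()
    sign_constraints: dict = field(default_factory=dict)
    value_constraints: dict = field(default_factory=dict)
    fixed_diffusion: dict = field(default_factory=dict)
    fixed_ratio: float | None = None
    in_phase: tuple = ()
    out_of_phase: tuple = ()

    def __post_init__(self):
        self.forced_edges = frozenset(map(tuple, self.forced_edges))
        self.zero_edges = frozenset(map(tuple, self.zero_edges))
        self.sign_constraints = {tuple(k): int(v) for k, v in self.sign_constraints.items()}
        self.value_constraints = {tuple(k): float(v) for k, v in self.value_constraints.items()}
        if self.forced_edges & self.zero_edges:
            raise ValueError("an edge cannot be both forced and forced-zero")
        for e, v in self.value_constraints.items():
            s = self.sign_constraints.get(e)
            if s is not None and np.sign(v) != s:
                raise ValueError(f"conflicting sign and value constraints on edge {e}")
        for e in itertools.chain(self.sign_constraints, self.value_constraints):
            if e in self.zero_edges:
                raise ValueError(f"sign/value constraint on forced-zero edge {e}")

    def resolved_phases(self, nodes) -> tuple[list[list[int]], list[tuple[int, int]]]:
        groups = [[_resolve_node(r, nodes) for r in grp] for grp in self.in_phase]
        pairs = [tuple(_resolve_node(r, nodes) for r in pr) for pr in self.out_of_phase]
        return groups, pairs

    def effective_sign(self, edge: Edge) -> int | None:
        v = self.value_constraints.get(edge)
        if v is not None:
            return int(np.sign(v))
        return self.sign_constraints.get(edge)

    def has_phase_constraints(self) -> bool:
        return bool(self.in_phase or self.out_of_phase)


@dataclass(frozen=True)
class DiffusionRegime:
    """How diffusion coefficients are chosen during the existence tests.

    kind:
        ``free``      each diffusible ``d_i`` sampled independently in (0, 1);
        ``equal``     all diffusible coefficients equal;
        ``fixed``     given values (or a given two-node ratio);
        ``universal`` one rate set must pattern across the whole probe set
                      of ratios (equal, far below and far above one).
    """

    kind: str = "free"
    values: tuple = ()
    ratio: float | None = None
    probe_ratios: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0, 100.0)

    def __post_init__(self):
        if self.kind not in {"free", "equal", "fixed", "universal"}:
            raise ValueError(f"unknown regime kind {self.kind!r}")
        if self.kind == "universal":
            r = np.array(self.probe_ratios)
            if not ((r == 1).any() and (r < 1).any() and (r > 1).any()):
                raise ValueError("universal probe set must include equal, <<1 and >>1 ratios")

    def engine_regime(self):
        if self.kind == "fixed":
            if self.ratio is not None:
                return ("ratio", self.ratio)
            return ("fixed", np.asarray(self.values, dtype=float))
        return (self.kind,)


@dataclass
class ScreenOptions:
    """Sampling and decision parameters of the screen."""

    budget: int = 20000
    chunk: int = 4000
    seed: int = 0
    stability: str = "strict"
    wavelength_selection: bool = True
    rate_high: float = 0.5
    diff_high: float = 1.0
    q2_grid: np.ndarray = field(default_factory=lambda: np.logspace(-3, 3, 32))
    probe_ratios: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0, 100.0)
    classify: bool = True
    robustness_samples: int = 2000
    phase_tries: int = 8
    max_topologies: int = 1 << 20   # cap for large (5-node) screens

    def sampler(self) -> eng.SamplerOptions:
        return eng.SamplerOptions(
            budget=self.budget,
            chunk=self.chunk,
            rate_high=self.rate_high,
            diff_high=self.diff_high,
            stability=self.stability,
            wavelength_selection=self.wavelength_selection,
            q2_grid=self.q2_grid,
            probe_ratios=self.probe_ratios,
        )


@dataclass
class RobustnessOptions:
    """Monte-Carlo volume estimate of the Turing space.

    The rate box defaults to (-0.5, 0.5) and the diffusion box to (0, 1):
    a unit-side multidimensional parameter space, so the estimate is the
    probability of randomly picking pattern-forming parameters.
    """

    rate_limits: tuple[float, float] = (-0.5, 0.5)
    diffusion_limits: tuple[float, float] = (0.0, 1.0)
    n_samples: int = 20000
    seed: int = 0

    def __post_init__(self):
        for lo, hi in (self.rate_limits, self.diffusion_limits):
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError("box limits must be finite with lower < upper")


@dataclass
class RobustnessEstimate:
    value: float
    stderr: float
    n_samples: int
    seed: int


@dataclass
class SurvivingTopology:
    """One sign assignment that passed steps 4-5, with its evidence."""

    topology: Topology
    witness_J: np.ndarray
    witness_D: np.ndarray
    q_star: float
    phase: tuple[int, ...]
    strict_stable: bool
    robustness: RobustnessEstimate | None = None

    def system(self) -> RDSystem:
        return RDSystem(self.witness_J, self.witness_D, topology=self.topology)


@dataclass
class CatalogEntry:
    """One screened network in the final catalog."""

    network: NetworkGraph
    key: str
    surviving: list[SurvivingTopology]
    phase_classes: dict  # phase tuple -> SurvivingTopology (representative)
    network_type: str | None
    n_topologies_total: int
    stable_topologies: int
    relative_robustness: float | None = None

    @property
    def n_surviving_raw(self) -> int:
        return len(self.surviving)

    @property
    def n_phase_classes(self) -> int:
        return len(self.phase_classes)

    def max_robustness(self) -> float | None:
        vals = [s.robustness.value for s in self.surviving if s.robustness is not None]
        return max(vals) if vals else None


@dataclass
class StepTable:
    """Per-step network and topology counts (step 1 through steps 5-6)."""

    rows: list  # (step, label, n_networks, n_topologies)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["step", "label", "n_networks", "n_topologies"])

    def counts(self, step: str) -> tuple[int, int]:
        for s, _, nn, nt in self.rows:
            if s == step:
                return nn, nt
        raise KeyError(step)


@dataclass
class ScreenResult:
    entries: list[CatalogEntry]
    step_table: StepTable
    seed: int
    options: ScreenOptions
    n_surviving_raw: int = 0

    @property
    def n_networks(self) -> int:
        return len(self.entries)


# ---------------------------------------------------------------------------
# step 6 helpers: topology enumeration and specs
# ---------------------------------------------------------------------------

def enumerate_topologies(net: NetworkGraph, constraints: ConstraintSet | None = None):
    """Yield all sign assignments consistent with the constraints.

    Count equals ``2 ** (k - #sign-constrained edges)``; edges ordered
    row-major, free signs enumerated as bit strings (minus sign first).
    """
    constraints = constraints or ConstraintSet()
    edges = net.sorted_edges()
    fixed = {}
    free = []
    for e in edges:
        s = constraints.effective_sign(e)
        if s is not None:
            fixed[e] = s
        else:
            free.append(e)
    for bits in range(2 ** len(free)):
        signs = dict(fixed)
        for pos, e in enumerate(free):
            signs[e] = +1 if (bits >> pos) & 1 else -1
        yield Topology(net, signs)


def n_free_signs(net: NetworkGraph, constraints: ConstraintSet | None = None) -> int:
    constraints = constraints or ConstraintSet()
    return sum(1 for e in net.edges if constraints.effective_sign(e) is None)


def _topology_spec(top: Topology, constraints: ConstraintSet | None = None) -> eng.TopologySpec:
    constraints = constraints or ConstraintSet()
    edges = top.network.sorted_edges()
    fixed = np.full(len(edges), np.nan)
    for i, e in enumerate(edges):
        v = constraints.value_constraints.get(e)
        if v is not None:
            fixed[i] = v
    return eng.TopologySpec(
        n_nodes=top.network.n_nodes,
        diffusible=top.network.diffusible_mask,
        edges=edges,
        signs=top.sign_vector(),
        fixed_values=fixed,
    )


# ---------------------------------------------------------------------------
# steps 4-5 as public operations
# ---------------------------------------------------------------------------

def topology_is_stable(
    top: Topology,
    options: ScreenOptions | None = None,
    seed: int | None = None,
    constraints: ConstraintSet | None = None,
):
    """Search for a rate magnitude assignment with a stable steady state.

    Returns ``(found, witness_J_or_None)``.  A miss after the full budget
    is a documented false-negative risk, not a proof of instability.
    """
    options = options or ScreenOptions()
    rng = eng.topology_rng(seed if seed is not None else options.seed, 0, 0, 0)
    w = eng.find_stable_witness(_topology_spec(top, constraints), options.sampler(), rng)
    return (w is not None), (w.J if w is not None else None)


def _phase_filter_from_constraints(top, constraints, options):
    if constraints is None or not constraints.has_phase_constraints():
        return None
    groups, pairs = constraints.resolved_phases(top.network.nodes)

    def check(w: eng.Witness) -> bool:
        ph = phase_pattern(RDSystem(w.J, w.D))
        for grp in groups:
            if len({ph[i] for i in grp}) > 1:
                return False
        for (a, b) in pairs:
            if ph[a] == ph[b]:
                return False
        return True

    return check


def topology_turing_capable(
    top: Topology,
    regime: DiffusionRegime | None = None,
    options: ScreenOptions | None = None,
    seed: int | None = None,
    constraints: ConstraintSet | None = None,
):
    """Search for parameters passing stability plus diffusion-driven
    instability under the given regime.  Returns ``(found, witness)``.

    Under the universal regime a single rate set must pattern at every
    probe ratio; in the permissive criterion
    (``wavelength_selection=False``) a witness with a stable Jacobian and
    an unstable immobile sub-block is attempted first, since it certifies
    instability in the ``q -> infinity`` limit for every positive
    diffusion choice.
    """
    options = options or ScreenOptions()
    regime = regime or DiffusionRegime("free")
    spec = _topology_spec(top, constraints)
    sampler = options.sampler()
    rng = eng.topology_rng(seed if seed is not None else options.seed, 0, 0, 1)
    phase_filter = _phase_filter_from_constraints(top, constraints, options)

    if regime.kind == "universal":
        if not options.wavelength_selection:
            # analytic capacitor certificate: stable J, unstable immobile block
            w = _capacitor_certificate(spec, sampler, rng)
            if w is not None:
                return True, w
        flags = eng.classification_flags(spec, sampler, rng)
        if flags["universal_capable"]:
            w = eng.find_turing_witness(spec, ("equal",), sampler, rng, phase_filter,
                                        options.phase_tries)
            return True, w
        return False, None

    w = eng.find_turing_witness(spec, regime.engine_regime(), sampler, rng,
                                phase_filter, options.phase_tries)
    return (w is not None), w


def _capacitor_certificate(spec, sampler, rng):
    opts = replace_sampler(sampler, wavelength_selection=False)
    k = len(spec.edges)
    drawn = 0
    while drawn < opts.budget:
        n = min(opts.chunk, opts.budget - drawn)
        mags = rng.uniform(0.0, opts.rate_high, size=(n, k)).clip(min=1e-12)
        drawn += n
        J = spec.assemble(mags)
        coeffs = eng.char_coeffs_batch(J)
        stable = eng.rh_strict_batch(coeffs)
        hot_block = ~eng.block_ok_batch(J, spec.diffusible, opts.block_tol)
        hit = stable & hot_block
        if hit.any():
            i = int(np.argmax(hit))
            D = np.zeros(spec.n_nodes)
            D[np.flatnonzero(spec.diffusible)] = 0.5
            return eng.Witness(J[i], D, ("certificate",), strict_stable=True)
    return None


def replace_sampler(s: eng.SamplerOptions, **kw) -> eng.SamplerOptions:
    return replace(s, **kw)


# ---------------------------------------------------------------------------
# step 6: phases, classification, robustness
# ---------------------------------------------------------------------------

_FALLBACK_Q2 = 1e6


def phase_pattern(sys: RDSystem) -> tuple[int, ...]:
    """Predicted in-phase / out-of-phase signature of the growing mode.

    Signs of the real parts of the dominant eigenvector of
    ``J - q_star^2 D``, normalised so the first diffusible node is ``+``.
    Nodes sharing a sign are predicted in phase.  When the growth maximum
    sits in the ``q -> infinity`` limit the eigenvector is evaluated at a
    large finite ``q^2`` instead.
    """
    disp = dispersion(sys.J, sys.D)
    q2 = disp.q_star if np.isfinite(disp.q_star) else _FALLBACK_Q2
    M = sys.J - q2 * np.diag(sys.D)
    vals, vecs = np.linalg.eig(M)
    v = vecs[:, np.argmax(vals.real)].real
    first_diff = int(np.flatnonzero(sys.diffusible_mask)[0]) if sys.diffusible_mask.any() else 0
    if v[first_diff] < 0:
        v = -v
    return tuple(+1 if x > 0 else -1 for x in v)


def classify_network(entry: CatalogEntry, options: ScreenOptions | None = None,
                     constraints: ConstraintSet | None = None,
                     seed: int | None = None) -> str:
    """Type label for a network that already passed steps 4-5.

    III if some surviving topology patterns under the universal regime,
    else II if some patterns with equal diffusivities, else I.
    """
    options = options or ScreenOptions()
    sampler = options.sampler()
    base_seed = seed if seed is not None else options.seed
    any_equal = False
    for t_idx, surv in enumerate(entry.surviving):
        spec = _topology_spec(surv.topology, constraints)
        rng = eng.topology_rng(base_seed, 9, t_idx, 2)
        flags = eng.classification_flags(spec, sampler, rng)
        if flags["universal_capable"]:
            return "III"
        any_equal |= flags["equal_capable"]
    return "II" if any_equal else "I"


def robustness(
    top: Topology,
    regime: DiffusionRegime | None = None,
    opts: RobustnessOptions | None = None,
    constraints: ConstraintSet | None = None,
    options: ScreenOptions | None = None,
) -> RobustnessEstimate:
    """Monte-Carlo Turing-space volume of one topology, with binomial SE."""
    opts = opts or RobustnessOptions()
    regime = regime or DiffusionRegime("free")
    options = options or ScreenOptions()
    sampler = options.sampler()
    sampler = replace_sampler(
        sampler,
        rate_high=opts.rate_limits[1],
        diff_high=opts.diffusion_limits[1],
        stability="strict",  # marginal sets have zero volume
    )
    spec = _topology_spec(top, constraints)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=opts.seed, spawn_key=(3,)))
    hits, n = eng.robustness_fraction(spec, regime.engine_regime(), opts.n_samples, sampler, rng)
    p = hits / n
    return RobustnessEstimate(p, math.sqrt(max(p * (1 - p), 1e-12) / n), n, opts.seed)


# ---------------------------------------------------------------------------
# minimum diffusion ratio
# ---------------------------------------------------------------------------

def min_diffusion_ratio(
    top: Topology,
    constraints: ConstraintSet | None = None,
    options: ScreenOptions | None = None,
    r_bounds: tuple[float, float] = (1e-4, 1e4),
    tol: float = 1e-4,
    n_scan: int = 65,
    seed: int | None = None,
) -> float | None:
    """Infimum of d = d_2/d_1 over the constrained Turing space.

    Exactly two diffusible nodes are required.  When every rate is pinned
    by value constraints the feasibility test is deterministic; otherwise
    each probed ratio runs the existence sampler.  Returns ``None`` when
    no ratio is feasible and ``0.0`` when even the smallest scanned ratio
    is (diffusivity-unconstrained patterning).
    """
    options = options or ScreenOptions()
    spec = _topology_spec(top, constraints)
    if spec.n_diffusible != 2:
        raise ValueError("min_diffusion_ratio requires exactly two diffusible nodes")
    sampler = options.sampler()
    fully_fixed = not np.isnan(spec.fixed_values).any()
    base_seed = seed if seed is not None else options.seed

    if fully_fixed:
        J = spec.assemble(np.abs(spec.fixed_values)[None, :])
        coeffs = eng.char_coeffs_batch(J)
        if not sampler.stability_mask(coeffs)[0]:
            return None
        if sampler.wavelength_selection and not eng.block_ok_batch(J, spec.diffusible, sampler.block_tol)[0]:
            return None

        def feasible(r: float) -> bool:
            d = np.array([[1.0, r]])
            an = eng.an_poly_coeffs(J, spec.diffusible, d)
            return bool(eng.dip_mask(an, sampler.q2_grid)[0])
    else:
        def feasible(r: float) -> bool:
            rng = eng.topology_rng(base_seed, 5, 0, int(1e6 * np.log10(r) + 4e6))
            return eng.ratio_feasible(spec, r, sampler, rng)

    grid = np.logspace(np.log10(r_bounds[0]), np.log10(r_bounds[1]), n_scan)
    feas = [feasible(r) for r in grid]
    if not any(feas):
        return None
    first = int(np.argmax(feas))
    if first == 0:
        return 0.0
    lo, hi = grid[first - 1], grid[first]
    while hi - lo > tol:
        mid = math.sqrt(lo * hi)
        if feasible(mid):
            hi = mid
        else:
            lo = mid
    return float(hi)


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------

def _constraint_preserving_permutations(nodes, constraints: ConstraintSet):
    """Class-preserving permutations that also map the constraint
    structure onto itself; used for step-3 dedup in constrained screens."""
    perms = []
    for p in class_preserving_permutations(nodes):
        def mapped(eset):
            return frozenset((p[i], p[j]) for (i, j) in eset)

        if mapped(constraints.forced_edges) != constraints.forced_edges:
            continue
        if mapped(constraints.zero_edges) != constraints.zero_edges:
            continue
        sc = {(p[i], p[j]): s for (i, j), s in constraints.sign_constraints.items()}
        vc = {(p[i], p[j]): v for (i, j), v in constraints.value_constraints.items()}
        if sc != constraints.sign_constraints or vc != constraints.value_constraints:
            continue
        perms.append(p)
    return perms


def _screen_topology(spec, regime, sampler, rng, phase_filter, phase_tries):
    """Single pass deciding stability and capability for one topology.

    Returns (stable_found, witness-or-None); rates and diffusion are
    drawn jointly so a capability witness doubles as a stability witness.
    """
    k = len(spec.edges)
    m = spec.n_diffusible
    diff_idx = np.flatnonzero(spec.diffusible)
    stable_found = False
    drawn = 0
    while drawn < sampler.budget:
        n = min(sampler.chunk, sampler.budget - drawn)
        mags = rng.uniform(0.0, sampler.rate_high, size=(n, k)).clip(min=1e-12)
        d = eng._draw_diffusion(rng, regime, n, m, sampler.diff_high)
        drawn += n
        J = spec.assemble(mags)
        base, strict, turing = eng._turing_masks(spec, J, d, sampler)
        stable_found |= bool(base.any())
        if not turing.any():
            continue
        hits = np.flatnonzero(turing)
        for i in hits[: (phase_tries if phase_filter else 1)]:
            D = np.zeros(spec.n_nodes)
            D[diff_idx] = d[i]
            w = eng.Witness(J[i], D, ("turing", regime[0]), strict_stable=bool(strict[i]))
            if phase_filter is None or phase_filter(w):
                return stable_found, w
    return stable_found, None


def run_pipeline(
    nodes,
    k: int,
    constraints: ConstraintSet | None = None,
    regime: DiffusionRegime | None = None,
    options: ScreenOptions | None = None,
    seed: int | None = None,
) -> ScreenResult:
    """Execute steps 1-6 and return the catalog plus the step-count table.

    Networks are ordered by canonical key and topologies by sign bit
    string; all randomness derives from the single run seed.
    """
    nodes = tuple(nodes)
    constraints = constraints or ConstraintSet()
    regime = regime or DiffusionRegime("free")
    options = options or ScreenOptions()
    if seed is not None:
        options = replace(options, seed=seed)
    run_seed = options.seed
    sampler = options.sampler()

    if int(np.sum([n.diffusible for n in nodes])) < 2:
        raise ValueError("at least two diffusible nodes are required to form a pattern")

    rows = []
    n1 = count_networks(len(nodes), k)
    # step-1 topology total: free-sign count is k minus globally constrained
    # cells; per-network constrained cells vary, so use the unconstrained
    # bookkeeping 2^k unless constraints touch every candidate identically.
    step1_nets = list(enumerate_networks(nodes, k, constraints.forced_edges, constraints.zero_edges))
    n1 = len(step1_nets) if (constraints.forced_edges or constraints.zero_edges) else n1
    t1 = sum(2 ** n_free_signs(net, constraints) for net in step1_nets)
    rows.append(("step1", "minimal systems", n1, t1))

    step2 = [net for net in step1_nets if passes_connectivity_filter(net)]
    t2 = sum(2 ** n_free_signs(net, constraints) for net in step2)
    rows.append(("step2", "strongly connected", len(step2), t2))

    perms = _constraint_preserving_permutations(nodes, constraints)
    step3 = dedup_networks(step2, perms)
    t3 = sum(2 ** n_free_signs(net, constraints) for net in step3)
    rows.append(("step3", "non-symmetrical", len(step3), t3))

    if t3 > options.max_topologies:
        raise ValueError(
            f"{t3} topologies exceed the configured cap {options.max_topologies}; "
            "add constraints to simplify the screen"
        )

    stable_networks = 0
    stable_topologies = 0
    raw_survivors = 0
    entries: list[CatalogEntry] = []

    for net_idx, net in enumerate(step3):
        phase_groups_filter = None
        net_stable = False
        net_stable_topos = 0
        surviving: list[SurvivingTopology] = []
        for topo_idx, top in enumerate(enumerate_topologies(net, constraints)):
            spec = _topology_spec(top, constraints)
            rng = eng.topology_rng(run_seed, net_idx, topo_idx, 1)
            phase_filter = _phase_filter_from_constraints(top, constraints, options)
            stable_found, w = _screen_topology(
                spec, regime.engine_regime(), sampler, rng, phase_filter, options.phase_tries
            )
            if stable_found:
                net_stable = True
                net_stable_topos += 1
            if w is None:
                continue
            sys = RDSystem(w.J, w.D)
            disp = dispersion(w.J, w.D)
            ph = phase_pattern(sys)
            surviving.append(
                SurvivingTopology(
                    topology=top,
                    witness_J=w.J,
                    witness_D=w.D,
                    q_star=disp.q_star,
                    phase=ph,
                    strict_stable=w.strict_stable,
                )
            )
        stable_networks += int(net_stable)
        stable_topologies += net_stable_topos
        if not surviving:
            continue
        raw_survivors += len(surviving)
        phase_classes: dict = {}
        for s in surviving:
            phase_classes.setdefault(s.phase, s)
        entry = CatalogEntry(
            network=net,
            key=canonical_key(net, perms).key,
            surviving=surviving,
            phase_classes=phase_classes,
            network_type=None,
            n_topologies_total=2 ** n_free_signs(net, constraints),
            stable_topologies=net_stable_topos,
        )
        entries.append(entry)

    rows.append(("step4", "stable", stable_networks, stable_topologies))
    phase_total = sum(e.n_phase_classes for e in entries)
    rows.append(("step5_6", "reaction-diffusion", len(entries), phase_total))

    if options.classify:
        for entry in entries:
            entry.network_type = classify_network(entry, options, constraints, seed=run_seed)

    if options.robustness_samples > 0:
        for e_idx, entry in enumerate(entries):
            for s_idx, surv in enumerate(entry.surviving):
                ropts = RobustnessOptions(
                    n_samples=options.robustness_samples,
                    seed=int((run_seed * 1000003 + e_idx * 101 + s_idx) % (2**31 - 1)),
                )
                surv.robustness = robustness(surv.topology, regime, ropts, constraints, options)
        best = max((e.max_robustness() or 0.0) for e in entries) if entries else 0.0
        for entry in entries:
            mr = entry.max_robustness()
            entry.relative_robustness = (mr / best) if (mr is not None and best > 0) else None

    result = ScreenResult(
        entries=entries,
        step_table=StepTable(rows),
        seed=run_seed,
        options=options,
        n_surviving_raw=raw_survivors,
    )
    return result
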
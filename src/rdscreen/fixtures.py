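"""Built-in screen configurations for the worked biological systems.

Each fixture resolves to a :class:`~rdscreen.io.RunConfig` (a runnable
screen) or, for ``type3_capacitor``, a concrete :class:`~rdscreen.lsa.RDSystem`.

Fixtures
--------
two_node
    The classical completely connected two-reactant control (k = 4);
    exactly one network with the activator-inhibitor (in-phase) and
    substrate-depleted (out-of-phase) surviving topologies.
three_node_full / four_node_full
    The unconstrained minimal catalogs: 3 nodes (2 diffusible) with
    k = 6, and 4 nodes (2 diffusible) with k = 7.
nodal_lefty
    Extension of the Nodal/Lefty activator-inhibitor pair with a
    non-diffusible signalling node (pSmad2/3 readout).  Constraints: a
    positive Nodal <-> signalling loop, signalling promotes Lefty, the
    negative self-edges of Nodal and Lefty pinned to measured clearance
    rate constants (ratio ~ 0.55, the biologically anchored quantity;
    values rescaled to the screen's rate box and configurable), and an
    in-phase Nodal/Lefty requirement.
bsw_three_node
    The three-node BMP/Sox9/Wnt digit patterning network with its known
    interaction signs and the out-of-phase Sox9 requirement.
bsw_five_node
    The five-node extension with explicit pSmad1/5/8 and beta-catenin
    nodes; a heavily constrained 5-node screen (constraints keep the
    topology count tractable).
yeast_ip
    Extension of the engineered yeast cytokinin (IP) sender-receiver
    module: the positive feedback hormone -> receptor -> synthase ->
    hormone is forced, the hormone's decay is part of the engineered
    module, diffusible nodes interact only through non-diffusible
    factors, diffusible self-regulation must be inhibitory, and the
    synthase (an enzymatic production step) carries no self-regulation.
type3_capacitor
    A hand-built three-node system whose non-diffusible node carries a
    positive self-loop: the Jacobian is stable while the immobile
    sub-block is not, so spatial modes grow in the large wave-number
    limit for every positive diffusion choice.
"""

from __future__ import annotations

import numpy as np

from .io import RunConfig
from .lsa import RDSystem
from .netspace import make_nodes
from .screen import ConstraintSet, DiffusionRegime

__all__ = ["FIXTURE_NAMES", "fixture"]

# rescaled zebrafish clearance rate constants (per-minute-like units);
# the screen-relevant quantity is their ratio ~ 0.5545
_NODAL_CLEARANCE = 0.11
_LEFTY_CLEARANCE = 0.061


def _two_node() -> RunConfig:
    return RunConfig(
        nodes=make_nodes([True, True], ["v", "w"]),
        k=4,
        description="classical two-reactant control: one completely connected network",
    )


def _three_node_full() -> RunConfig:
    return RunConfig(
        nodes=make_nodes([True, True, False], ["v", "w", "u"]),
        k=6,
        description="minimal 3-node catalog: two diffusible signals, one cell-autonomous factor",
    )


def _four_node_full() -> RunConfig:
    return RunConfig(
        nodes=make_nodes([True, True, False, False], ["v", "w", "u1", "u2"]),
        k=7,
        description="minimal 4-node catalog: two signals, two cell-autonomous factors",
    )


def _nodal_lefty() -> RunConfig:
    # 0 = Nodal (diffusible), 1 = Lefty (diffusible), 2 = pSmad signalling (immobile)
    return RunConfig(
        nodes=make_nodes([True, True, False], ["Nodal", "Lefty", "Signal"]),
        k=6,
        constraints=ConstraintSet(
            forced_edges={(2, 0), (0, 2), (1, 2), (0, 0), (1, 1)},
            sign_constraints={(2, 0): +1, (0, 2): +1, (1, 2): +1},
            value_constraints={(0, 0): -_NODAL_CLEARANCE, (1, 1): -_LEFTY_CLEARANCE},
            in_phase=(("Nodal", "Lefty"),),
        ),
        description="Nodal/Lefty + signalling screen with measured clearance constraints",
    )


def _bsw_three_node() -> RunConfig:
    # 0 = BMP, 1 = Wnt (diffusible), 2 = Sox9 (immobile)
    return RunConfig(
        nodes=make_nodes([True, True, False], ["BMP", "Wnt", "Sox9"]),
        k=6,
        constraints=ConstraintSet(
            forced_edges={(2, 0), (2, 1), (0, 2), (1, 2), (0, 0), (1, 1)},
            sign_constraints={
                (2, 0): +1,   # BMP signalling promotes Sox9
                (2, 1): -1,   # Wnt signalling represses Sox9
                (0, 2): -1,   # Sox9 represses BMP
                (1, 2): -1,   # Sox9 represses Wnt
                (0, 0): -1,
                (1, 1): -1,
            },
            out_of_phase=(("Sox9", "BMP"), ("Sox9", "Wnt")),
        ),
        description="three-node BMP/Sox9/Wnt digit patterning topology",
    )


def _bsw_five_node() -> RunConfig:
    # 0 = BMP, 1 = Wnt (diffusible); 2 = pSmad1/5/8, 3 = beta-catenin, 4 = Sox9
    return RunConfig(
        nodes=make_nodes([True, True, False, False, False],
                         ["BMP", "Wnt", "pSmad", "bCat", "Sox9"]),
        k=10,
        constraints=ConstraintSet(
            forced_edges={(2, 0), (4, 2), (3, 1), (0, 0), (1, 1), (0, 2), (1, 4), (2, 3)},
            zero_edges={(0, 1), (1, 0), (4, 1), (4, 0), (0, 3), (0, 4), (1, 2), (1, 3),
                        (3, 0), (3, 2), (3, 3), (3, 4), (2, 1)},
            sign_constraints={
                (2, 0): +1,   # BMP activates its own transduction (pSmad)
                (4, 2): +1,   # pSmad promotes Sox9
                (3, 1): +1,   # Wnt activates beta-catenin
                (0, 0): -1,
                (1, 1): -1,
                (0, 2): -1,   # negative feedback pSmad -| BMP
                (1, 4): -1,   # negative feedback Sox9 -| Wnt
                (2, 3): -1,   # beta-catenin acts on Sox9 through pSmad
            },
            out_of_phase=(("Sox9", "Wnt"), ("Sox9", "BMP")),
            in_phase=(("Sox9", "pSmad"),),
        ),
        description="five-node BMP/Wnt/pSmad/beta-catenin/Sox9 digit patterning screen",
    )


def _yeast_ip() -> RunConfig:
    # 0 = IP hormone (diffusible), 1 = new hormone (diffusible),
    # 2 = receptor/transducer AtCRE1 (immobile), 3 = synthase AtIPT4 (immobile)
    return RunConfig(
        nodes=make_nodes([True, True, False, False],
                         ["IP", "Hormone2", "Receptor", "Synthase"]),
        k=7,
        constraints=ConstraintSet(
            # engineered positive feedback: IP -> receptor -> synthase -> IP,
            # plus the hormone's decay, part of the existing module
            forced_edges={(2, 0), (3, 2), (0, 3), (0, 0)},
            # hormones interact only through cell-autonomous factors; the
            # synthase is a pure production step without self-regulation
            zero_edges={(0, 1), (1, 0), (3, 3)},
            sign_constraints={(2, 0): +1, (3, 2): +1, (0, 3): +1,
                              (0, 0): -1, (1, 1): -1},
        ),
        # engineered production chains sit on the singular boundary of
        # rate space (several species driven by one regulator), so this
        # screen admits marginally stable (semistable) steady states
        stability="semistable",
        description="extension screen of the engineered yeast IP positive-feedback module",
    )


def _type3_capacitor() -> RDSystem:
    J = np.array([
        [-1.0, 0.0, 2.0],
        [0.0, -1.0, 2.0],
        [-1.0, -0.5, 0.25],
    ])
    return RDSystem(J, np.array([0.3, 0.7, 0.0]))


_FIXTURES = {
    "two_node": _two_node,
    "three_node_full": _three_node_full,
    "four_node_full": _four_node_full,
    "nodal_lefty": _nodal_lefty,
    "bsw_three_node": _bsw_three_node,
    "bsw_five_node": _bsw_five_node,
    "yeast_ip": _yeast_ip,
    "type3_capacitor": _type3_capacitor,
}

FIXTURE_NAMES = tuple(sorted(_FIXTURES))


def fixture(name: str):
    """Return the canned RunConfig (or RDSystem) for a named fixture."""
    try:
        factory = _FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; valid names: {', '.join(FIXTURE_NAMES)}"
        ) from None
    return factory()
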
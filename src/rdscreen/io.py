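"""Configuration parsing and catalog/report serialisation.

A screen is fully described by a JSON ``RunConfig`` (nodes, edge count,
constraints, diffusion regime, sampling options); a run is reproducible
from its config plus seed alone.  Catalogs serialise to JSON (the
authoritative format, with witnesses and seeds) and to CSV summaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .netspace import NetworkGraph, NodeSpec, make_nodes
from .screen import (
    CatalogEntry,
    ConstraintSet,
    DiffusionRegime,
    RobustnessEstimate,
    ScreenOptions,
    ScreenResult,
    StepTable,
    SurvivingTopology,
    Topology,
    run_pipeline,
)

__all__ = ["RunConfig", "parse_config", "write_config", "write_catalog",
           "load_catalog", "write_step_table"]


@dataclass
class RunConfig:
    """A fully serialisable description of one screen run."""

    nodes: tuple[NodeSpec, ...]
    k: int
    constraints: ConstraintSet = field(default_factory=ConstraintSet)
    regime: DiffusionRegime = field(default_factory=DiffusionRegime)
    budget: int = 20000
    seed: int = 0
    stability: str = "strict"
    description: str = ""

    def options(self, **overrides) -> ScreenOptions:
        kw = dict(budget=self.budget, seed=self.seed, stability=self.stability)
        kw.update(overrides)
        return ScreenOptions(**kw)

    def run(self, options: ScreenOptions | None = None) -> ScreenResult:
        opts = options or self.options()
        return run_pipeline(self.nodes, self.k, self.constraints, self.regime, opts)

    # -- JSON form -----------------------------------------------------
    def to_dict(self) -> dict:
        c = self.constraints
        return {
            "description": self.description,
            "nodes": [
                {"label": n.label or f"n{n.index}", "diffusible": n.diffusible}
                for n in self.nodes
            ],
            "k": self.k,
            "constraints": {
                "forced_edges": sorted(map(list, c.forced_edges)),
                "zero_edges": sorted(map(list, c.zero_edges)),
                "sign_constraints": [[list(e), s] for e, s in sorted(c.sign_constraints.items())],
                "value_constraints": [[list(e), v] for e, v in sorted(c.value_constraints.items())],
                "fixed_diffusion": {str(k_): v for k_, v in c.fixed_diffusion.items()},
                "fixed_ratio": c.fixed_ratio,
                "in_phase": [list(g) for g in c.in_phase],
                "out_of_phase": [list(p) for p in c.out_of_phase],
            },
            "regime": {
                "kind": self.regime.kind,
                "values": list(self.regime.values),
                "ratio": self.regime.ratio,
                "probe_ratios": list(self.regime.probe_ratios),
            },
            "sampling": {"budget": self.budget, "seed": self.seed, "stability": self.stability},
        }


_TOP_KEYS = {"description", "nodes", "k", "constraints", "regime", "sampling"}
_CONSTRAINT_KEYS = {"forced_edges", "zero_edges", "sign_constraints", "value_constraints",
                    "fixed_diffusion", "fixed_ratio", "in_phase", "out_of_phase"}
_REGIME_KEYS = {"kind", "values", "ratio", "probe_ratios"}
_SAMPLING_KEYS = {"budget", "seed", "stability"}


def _reject_unknown(d: dict, allowed: set, where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} at {where}")


def config_from_dict(data: dict) -> RunConfig:
    _reject_unknown(data, _TOP_KEYS, "top level")
    try:
        node_specs = data["nodes"]
        k = int(data["k"])
    except KeyError as exc:
        raise ValueError(f"missing required config key: {exc}") from exc
    for i, n in enumerate(node_specs):
        _reject_unknown(n, {"label", "diffusible"}, f"nodes[{i}]")
    nodes = make_nodes(
        [bool(n["diffusible"]) for n in node_specs],
        [n.get("label") for n in node_specs],
    )
    n_cells = len(nodes) ** 2
    if not 1 <= k <= n_cells:
        raise ValueError(f"k={k} invalid: must satisfy 1 <= k <= N*N = {n_cells}")

    cdata = data.get("constraints", {})
    _reject_unknown(cdata, _CONSTRAINT_KEYS, "constraints")
    constraints = ConstraintSet(
        forced_edges=frozenset(map(tuple, cdata.get("forced_edges", []))),
        zero_edges=frozenset(map(tuple, cdata.get("zero_edges", []))),
        sign_constraints={tuple(e): int(s) for e, s in cdata.get("sign_constraints", [])},
        value_constraints={tuple(e): float(v) for e, v in cdata.get("value_constraints", [])},
        fixed_diffusion={int(k_): float(v) for k_, v in cdata.get("fixed_diffusion", {}).items()},
        fixed_ratio=cdata.get("fixed_ratio"),
        in_phase=tuple(tuple(g) for g in cdata.get("in_phase", [])),
        out_of_phase=tuple(tuple(p) for p in cdata.get("out_of_phase", [])),
    )
    constraints.resolved_phases(nodes)  # validates node references

    rdata = data.get("regime", {})
    _reject_unknown(rdata, _REGIME_KEYS, "regime")
    regime_kw = dict(kind=rdata.get("kind", "free"))
    if rdata.get("values"):
        regime_kw["values"] = tuple(rdata["values"])
    if rdata.get("ratio") is not None:
        regime_kw["ratio"] = float(rdata["ratio"])
    if rdata.get("probe_ratios"):
        regime_kw["probe_ratios"] = tuple(rdata["probe_ratios"])
    regime = DiffusionRegime(**regime_kw)

    sdata = data.get("sampling", {})
    _reject_unknown(sdata, _SAMPLING_KEYS, "sampling")
    return RunConfig(
        nodes=nodes,
        k=k,
        constraints=constraints,
        regime=regime,
        budget=int(sdata.get("budget", 20000)),
        seed=int(sdata.get("seed", 0)),
        stability=str(sdata.get("stability", "strict")),
        description=data.get("description", ""),
    )


def parse_config(path) -> RunConfig:
    """Load and validate a JSON screen configuration."""
    with open(path) as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValueError(f"malformed JSON in {path}: line {exc.lineno}, column {exc.colno}: {exc.msg}") from exc
    try:
        return config_from_dict(data)
    except ValueError as exc:
        raise ValueError(f"invalid config {path}: {exc}") from exc


def write_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        json.dump(cfg.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# catalog serialisation
# ---------------------------------------------------------------------------

def _entry_to_dict(entry: CatalogEntry) -> dict:
    net = entry.network
    return {
        "key": entry.key,
        "nodes": [{"label": n.label or f"n{n.index}", "diffusible": n.diffusible} for n in net.nodes],
        "edges": sorted(map(list, net.edges)),
        "network_type": entry.network_type,
        "n_topologies_total": entry.n_topologies_total,
        "stable_topologies": entry.stable_topologies,
        "relative_robustness": entry.relative_robustness,
        "surviving": [
            {
                "signs": [[list(e), s] for e, s in sorted(t.topology.signs.items())],
                "witness_J": t.witness_J.tolist(),
                "witness_D": t.witness_D.tolist(),
                "q_star": t.q_star,
                "phase": list(t.phase),
                "strict_stable": t.strict_stable,
                "robustness": (
                    None if t.robustness is None else
                    {"value": t.robustness.value, "stderr": t.robustness.stderr,
                     "n_samples": t.robustness.n_samples, "seed": t.robustness.seed}
                ),
            }
            for t in entry.surviving
        ],
    }


def _entry_from_dict(d: dict) -> CatalogEntry:
    nodes = make_nodes([n["diffusible"] for n in d["nodes"]],
                       [n.get("label") for n in d["nodes"]])
    net = NetworkGraph(nodes, frozenset(map(tuple, d["edges"])))
    surviving = []
    for t in d["surviving"]:
        top = Topology(net, {tuple(e): int(s) for e, s in t["signs"]})
        rob = t.get("robustness")
        surviving.append(
            SurvivingTopology(
                topology=top,
                witness_J=np.array(t["witness_J"]),
                witness_D=np.array(t["witness_D"]),
                q_star=float(t["q_star"]),
                phase=tuple(t["phase"]),
                strict_stable=bool(t["strict_stable"]),
                robustness=None if rob is None else RobustnessEstimate(
                    rob["value"], rob["stderr"], rob["n_samples"], rob["seed"]),
            )
        )
    phase_classes = {}
    for s in surviving:
        phase_classes.setdefault(s.phase, s)
    return CatalogEntry(
        network=net,
        key=d["key"],
        surviving=surviving,
        phase_classes=phase_classes,
        network_type=d.get("network_type"),
        n_topologies_total=d["n_topologies_total"],
        stable_topologies=d["stable_topologies"],
        relative_robustness=d.get("relative_robustness"),
    )


def write_catalog(result_or_entries, path, fmt: str = "json", seed: int | None = None) -> None:
    """Write a catalog as JSON (full, replayable) or CSV (summary).

    The CSV has one row per network: canonical key, type, topology
    counts, best robustness with its standard error.
    """
    if isinstance(result_or_entries, ScreenResult):
        entries = result_or_entries.entries
        seed = result_or_entries.seed if seed is None else seed
    else:
        entries = list(result_or_entries)
    if fmt == "json":
        payload = {
            "seed": seed,
            "n_networks": len(entries),
            "entries": [_entry_to_dict(e) for e in entries],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
            fh.write("\n")
    elif fmt == "csv":
        rows = []
        for e in entries:
            best = e.max_robustness()
            se = None
            if best is not None:
                for s in e.surviving:
                    if s.robustness is not None and s.robustness.value == best:
                        se = s.robustness.stderr
                        break
            rows.append({
                "key": e.key,
                "type": e.network_type,
                "n_surviving_topologies": e.n_surviving_raw,
                "n_phase_classes": e.n_phase_classes,
                "robustness": best,
                "robustness_se": se,
            })
        pd.DataFrame(rows).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown catalog format {fmt!r}")


def load_catalog(path) -> tuple[list[CatalogEntry], int | None]:
    with open(path) as fh:
        payload = json.load(fh)
    return [_entry_from_dict(d) for d in payload["entries"]], payload.get("seed")


def write_step_table(table: StepTable, path) -> None:
    table.to_frame().to_csv(path, index=False)
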
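"""Subcircuit wiring, coupling vectors and closed-form steady states.

The three dorsal-horn motifs analysed here are feedforward:

* ``simple``  -- gate control: Abeta -> {I, E}, I -| E; output E.
* ``static``  -- Abeta -> {I1, I2, E}, I1 -| E, I2 -| E; output E.
* ``dynamic`` -- Abeta -> {I1, E1, I2, E2}, I1 -| E1, E1 -> E2, I2 -| E2;
  output E2.

Because the graphs are acyclic, the steady state for a constant Abeta rate is
computed in one topological sweep with no fixed-point iteration:

    V_x^ss = V_x,rest + sum_y (+/-) g_yx * f_y + g_Abx * f_Ab.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .populations import EXCITATORY, INHIBITORY, PopulationParams

__all__ = [
    "Connection",
    "SubcircuitSpec",
    "SteadyState",
    "simple_circuit",
    "static_circuit",
    "dynamic_circuit",
    "get_circuit",
    "steady_state",
    "circuit_from_config",
]

ABETA = "Abeta"


@dataclass(frozen=True)
class Connection:
    """A signed, weighted connection ``source -> target``.

    ``source`` is a population id or ``"Abeta"``; ``sign`` is +1 for
    excitatory and -1 for inhibitory coupling; ``name`` is the coupling
    parameter keyed into a coupling vector.
    """

    source: str
    target: str
    sign: int
    name: str


@dataclass(frozen=True)
class SubcircuitSpec:
    """Wiring template for one subcircuit.

    ``hierarchy`` orders the coupling parameters so that the feasible
    interval of each parameter depends only on the ones before it; it is the
    canonical coordinate order for coupling vectors.
    """

    name: str
    populations: tuple[tuple[str, PopulationParams], ...]
    connections: tuple[Connection, ...]
    output: str
    hierarchy: tuple[str, ...]
    f_range: tuple[float, float] = (10.0, 20.0)
    low_range: tuple[float, float] = (0.0, 10.0)

    def __post_init__(self) -> None:
        ids = [pid for pid, _ in self.populations]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate population ids")
        names = [c.name for c in self.connections]
        if sorted(names) != sorted(self.hierarchy):
            raise ValueError("hierarchy must be a permutation of coupling names")
        for pid in ids:
            if not any(c.source == ABETA and c.target == pid for c in self.connections):
                raise ValueError(f"population {pid} lacks an Abeta connection")
        if self.output not in ids:
            raise ValueError("output population not in circuit")
        self._check_dag()

    def _check_dag(self) -> None:
        order = {pid: i for i, pid in enumerate(self.topological_order())}
        for c in self.connections:
            if c.source != ABETA and order[c.source] >= order[c.target]:
                raise ValueError("connection graph is not feedforward")

    @property
    def dim(self) -> int:
        return len(self.hierarchy)

    @property
    def population_ids(self) -> tuple[str, ...]:
        return tuple(pid for pid, _ in self.populations)

    def params(self, pid: str) -> PopulationParams:
        for qid, p in self.populations:
            if qid == pid:
                return p
        raise KeyError(pid)

    def topological_order(self) -> tuple[str, ...]:
        """Population ids sorted so presynaptic populations come first."""
        ids = list(self.population_ids)
        deps = {
            pid: {c.source for c in self.connections
                  if c.target == pid and c.source != ABETA}
            for pid in ids
        }
        out: list[str] = []
        while ids:
            ready = [p for p in ids if deps[p] <= set(out)]
            if not ready:
                raise ValueError("cycle in connection graph")
            out.extend(ready)
            ids = [p for p in ids if p not in ready]
        return tuple(out)

    def incoming(self, pid: str) -> tuple[Connection, ...]:
        return tuple(c for c in self.connections if c.target == pid)

    @property
    def output_abeta(self) -> str:
        """Name of the Abeta coupling onto the output population."""
        for c in self.connections:
            if c.source == ABETA and c.target == self.output:
                return c.name
        raise AssertionError("unreachable: output has an Abeta connection")

    def coupling_array(self, g: Mapping[str, float]) -> np.ndarray:
        """Couplings as an array ordered by ``hierarchy``."""
        arr = np.array([float(g[k]) for k in self.hierarchy])
        if np.any(arr < 0):
            raise ValueError("couplings must be nonnegative")
        return arr

    def coupling_dict(self, arr: Sequence[float]) -> dict[str, float]:
        if len(arr) != self.dim:
            raise ValueError("coupling vector has wrong dimension")
        return {k: float(v) for k, v in zip(self.hierarchy, arr)}


@dataclass
class SteadyState:
    """Per-population steady voltages (mV) and rates (Hz) at fixed f_Ab."""

    f_ab: float
    ablated: frozenset[str]
    voltage: dict[str, float] = field(default_factory=dict)
    rate: dict[str, float] = field(default_factory=dict)


def steady_state(
    spec: SubcircuitSpec,
    g: Mapping[str, float],
    f_ab,
    ablated: Iterable[str] = (),
) -> SteadyState:
    """Closed-form steady state under constant Abeta drive.

    ``f_ab`` may be a scalar or an ndarray (the sweep used by the feasibility
    oracle); voltages/rates then hold arrays.  Ablated populations contribute
    rate 0 downstream and report V = V_rest.
    """
    ablated = frozenset(ablated)
    unknown = ablated - set(spec.population_ids)
    if unknown:
        raise ValueError(f"unknown population(s) in ablation set: {sorted(unknown)}")
    f_ab = np.asarray(f_ab, dtype=float)
    if np.any(f_ab < 0):
        raise ValueError("f_ab must be nonnegative")

    ss = SteadyState(f_ab=f_ab if f_ab.ndim else float(f_ab), ablated=ablated)
    for pid in spec.topological_order():
        pop = spec.params(pid)
        if pid in ablated:
            V = np.broadcast_to(pop.V_rest, f_ab.shape).astype(float)
            rate = np.zeros_like(V)
        else:
            V = np.full(f_ab.shape, pop.V_rest, dtype=float)
            for c in spec.incoming(pid):
                drive = f_ab if c.source == ABETA else ss.rate[c.source]
                V = V + c.sign * float(g[c.name]) * drive
            rate = pop.rate(V)
        if f_ab.ndim == 0:
            V, rate = float(V), float(rate)
        ss.voltage[pid] = V
        ss.rate[pid] = rate
    return ss


def _three_pop(name: str, inhibs: Sequence[str]) -> SubcircuitSpec:
    pops = [(i, INHIBITORY) for i in inhibs] + [("E", EXCITATORY)]
    conns = [Connection(ABETA, i, +1, f"g_Ab{i}") for i in inhibs]
    conns += [Connection(i, "E", -1, f"g_{i}E") for i in inhibs]
    conns.append(Connection(ABETA, "E", +1, "g_AbE"))
    if name == "simple":
        hierarchy = ("g_AbI", "g_IE", "g_AbE")
    else:
        hierarchy = ("g_AbI1", "g_AbI2", "g_AbE", "g_I1E", "g_I2E")
    return SubcircuitSpec(
        name=name,
        populations=tuple(pops),
        connections=tuple(conns),
        output="E",
        hierarchy=hierarchy,
    )


def simple_circuit() -> SubcircuitSpec:
    """Gate-control motif: one inhibitory, one excitatory population."""
    return _three_pop("simple", ["I"])


def static_circuit() -> SubcircuitSpec:
    """Static-allodynia motif: two inhibitory populations gate one E."""
    return _three_pop("static", ["I1", "I2"])


def dynamic_circuit() -> SubcircuitSpec:
    """Dynamic-allodynia motif: two gated excitatory populations in series."""
    pops = (
        ("I1", INHIBITORY),
        ("E1", EXCITATORY),
        ("I2", INHIBITORY),
        ("E2", EXCITATORY),
    )
    conns = (
        Connection(ABETA, "I1", +1, "g_AbI1"),
        Connection(ABETA, "E1", +1, "g_AbE1"),
        Connection(ABETA, "I2", +1, "g_AbI2"),
        Connection(ABETA, "E2", +1, "g_AbE2"),
        Connection("I1", "E1", -1, "g_I1E1"),
        Connection("E1", "E2", +1, "g_E1E2"),
        Connection("I2", "E2", -1, "g_I2E2"),
    )
    hierarchy = ("g_AbI1", "g_AbI2", "g_I1E1", "g_AbE1", "g_E1E2", "g_I2E2", "g_AbE2")
    return SubcircuitSpec(
        name="dynamic",
        populations=pops,
        connections=conns,
        output="E2",
        hierarchy=hierarchy,
    )


_BUILTIN = {
    "simple": simple_circuit,
    "static": static_circuit,
    "dynamic": dynamic_circuit,
}


def get_circuit(name: str) -> SubcircuitSpec:
    try:
        return _BUILTIN[name]()
    except KeyError:
        raise KeyError(f"unknown circuit {name!r}; choose from {sorted(_BUILTIN)}")


def circuit_from_config(path) -> SubcircuitSpec:
    """Load a custom circuit from a YAML/JSON declarative config.

    Schema::

        name: mycircuit
        output: E
        f_range: [10, 20]          # optional
        populations:
          - {id: I, role: inhibitory}            # built-in defaults, or
          - {id: E, role: excitatory, m: 50, alpha: 7.9, beta: -17,
             V_rest: -60, tau: 0.024}
        connections:
          - {source: Abeta, target: I, sign: 1, name: g_AbI}
          - {source: I, target: E, sign: -1, name: g_IE}
        hierarchy: [g_AbI, g_IE]
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    pops = []
    for p in cfg["populations"]:
        if set(p) <= {"id", "role"}:
            base = INHIBITORY if p["role"] == "inhibitory" else EXCITATORY
            pops.append((p["id"], base))
        else:
            pops.append(
                (
                    p["id"],
                    PopulationParams(
                        role=p["role"], m=p["m"], alpha=p["alpha"], beta=p["beta"],
                        V_rest=p["V_rest"], tau=p["tau"],
                    ),
                )
            )
    conns = tuple(
        Connection(c["source"], c["target"], int(c["sign"]), c["name"])
        for c in cfg["connections"]
    )
    return SubcircuitSpec(
        name=cfg["name"],
        populations=tuple(pops),
        connections=conns,
        output=cfg["output"],
        hierarchy=tuple(cfg["hierarchy"]),
        f_range=tuple(cfg.get("f_range", (10.0, 20.0))),
    )
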
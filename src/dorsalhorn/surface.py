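"""The allodynia surface and shortest paths to it.

A subcircuit produces allodynia when its output excitatory population can
cross firing threshold for at least one innocuous Abeta rate in [10, 20] Hz.
Solving the threshold condition for the Abeta coupling onto the output
population defines a height function over the remaining couplings,

    h(g_rest) = min_{f in [10,20]} [dV_thr + (inhibitory - excitatory
                input to the output at rate f)] / f,

and the allodynia surface S is the graph ``g_out = h(g_rest)``.  A coupling
vector is allodynic iff its output-Abeta coordinate is at least the height.

The shortest path from an APS point to S is computed in NORMALIZED
coordinates (distances across couplings are only comparable as fractions of
their APS ranges).  Instead of constrained optimization on the implicit
surface, the equality constraint is eliminated: the surface is parameterized
by (all non-output couplings, f), with the output coordinate set to the
threshold expression at that f.  Because the allodynic region is the closed
set above S and the lifted surface S* (no min over f) lies inside it, the
minimum over S* equals the minimum over S.  Multi-start bounded local
optimization then recovers the global minimum with high probability, and the
non-global converged starts provide the nearby local minima reported
alongside it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .circuits import SubcircuitSpec
from .constraints import NormalizationBox, extremize_over_stimulus, normalize

__all__ = [
    "SurfacePoint",
    "ShortestPathResult",
    "surface_height",
    "is_allodynic",
    "shortest_path",
    "shortest_paths",
]


def _gap_terms(spec: SubcircuitSpec, g_rest: Mapping[str, float]):
    """Return cost(f): net non-output drive that the output-Abeta input must
    overcome, i.e. dV_thr + inhibitory terms - excitatory terms, at rate f.

    Evaluates the presynaptic chain of the output population under control
    (no ablation) conditions; vectorized over f.
    """
    out = spec.output
    pop_out = spec.params(out)
    dv_thr = pop_out.V_thr - pop_out.V_rest

    sources = [c for c in spec.incoming(out) if c.source != "Abeta"]

    def cost(f):
        f = np.asarray(f, dtype=float)
        # rates of presynaptic populations in topological order
        rates: dict[str, np.ndarray] = {}
        for pid in spec.topological_order():
            if pid == out:
                continue
            pop = spec.params(pid)
            V = np.full(f.shape, pop.V_rest)
            for c in spec.incoming(pid):
                drv = f if c.source == "Abeta" else rates[c.source]
                V = V + c.sign * float(g_rest[c.name]) * drv
            rates[pid] = pop.rate(V)
        total = np.full(f.shape, dv_thr)
        for c in sources:
            total = total - c.sign * float(g_rest[c.name]) * rates[c.source]
        return total

    return cost


@dataclass(frozen=True)
class SurfacePoint:
    """A point on the allodynia surface with its minimizing stimulus."""

    raw: np.ndarray
    normalized: np.ndarray
    f_nearest: float
    residual: float


def surface_height(
    spec: SubcircuitSpec, g_rest: Mapping[str, float]
) -> tuple[float, float]:
    """Height of the allodynia surface over ``g_rest`` and its argmin f.

    ``g_rest`` holds every coupling except the output population's Abeta
    coupling (extra entries are ignored).  The height may be lowered below
    dV_thr/f by excitatory presynaptic input (dynamic circuit).
    """
    for name in spec.hierarchy:
        if name != spec.output_abeta and name not in g_rest:
            raise KeyError(f"missing coupling {name}")
        if name in g_rest and float(g_rest[name]) < 0:
            raise ValueError("couplings must be nonnegative")
    cost = _gap_terms(spec, g_rest)
    h, f_star = extremize_over_stimulus(
        lambda f: cost(f) / f, spec.f_range, "min"
    )
    return h, f_star


def is_allodynic(spec: SubcircuitSpec, g: Mapping[str, float]) -> bool:
    """True iff the output population can fire for some f in range."""
    if not isinstance(g, Mapping):
        g = spec.coupling_dict(np.asarray(g, dtype=float))
    h, _ = surface_height(spec, g)
    return float(g[spec.output_abeta]) >= h


@dataclass
class ShortestPathResult:
    """Shortest normalized displacement from an APS point to the surface."""

    origin: np.ndarray                 # normalized coordinates
    surface_point: SurfacePoint
    displacement: np.ndarray
    length: float
    local_minima: list[SurfacePoint] = field(default_factory=list)
    local_lengths: list[float] = field(default_factory=list)
    factor: float = 1.5
    n_starts: int = 0
    n_converged: int = 0


def _surface_objective(spec, box, origin, out_idx, rest_idx):
    """Squared-distance objective over the reduced (g_rest_hat, f) space.

    Compiled to flat scalar arithmetic (the optimizer evaluates it ~1e5
    times per sample with finite-difference gradients; numpy-scalar
    overhead dominates otherwise).
    """
    import math

    names = spec.hierarchy
    zcol = {names[j]: i for i, j in enumerate(rest_idx)}  # z index per coupling
    lo_r = box.lo[rest_idx]
    rng_r = box.ranges[rest_idx]
    lo_o, rng_o = float(box.lo[out_idx]), float(box.ranges[out_idx])
    orig_r = origin[rest_idx]
    orig_o = float(origin[out_idx])

    out = spec.output
    pop_out = spec.params(out)
    dv_thr = pop_out.V_thr - pop_out.V_rest
    # upstream populations in topological order: (V_rest, beta, alpha, m/2,
    # abeta z-index, [(source order-position, z-index, sign), ...])
    chain = []
    order = [pid for pid in spec.topological_order() if pid != out]
    pos = {pid: i for i, pid in enumerate(order)}
    for pid in order:
        pop = spec.params(pid)
        ab = None
        syn = []
        for c in spec.incoming(pid):
            if c.source == "Abeta":
                ab = zcol[c.name]
            else:
                syn.append((pos[c.source], zcol[c.name], c.sign))
        chain.append((pop.V_rest, pop.beta, pop.alpha, 0.5 * pop.m, ab, syn))
    out_terms = [(pos[c.source], zcol[c.name], c.sign)
                 for c in spec.incoming(out) if c.source != "Abeta"]

    def gap_at(raw, f):
        rates = []
        for V_rest, beta, alpha, halfm, ab, syn in chain:
            V = V_rest + raw[ab] * f
            for src, col, sign in syn:
                V += sign * raw[col] * rates[src]
            rates.append(halfm * (1.0 + math.tanh((V - beta) / alpha)))
        total = dv_thr
        for src, col, sign in out_terms:
            total -= sign * raw[col] * rates[src]
        return total

    def unpack(z):
        g_rest_hat = np.asarray(z[:-1], dtype=float)
        f = float(z[-1])
        raw_rest = lo_r + g_rest_hat * rng_r
        g_out_raw = gap_at(raw_rest, f) / f
        return g_rest_hat, raw_rest, g_out_raw

    def obj(z):
        f = float(z[-1])
        val = 0.0
        raw = [0.0] * len(rest_idx)
        for i in range(len(rest_idx)):
            zi = float(z[i])
            raw[i] = lo_r[i] + zi * rng_r[i]
            dv = zi - orig_r[i]
            val += dv * dv
        g_out_raw = gap_at(raw, f) / f
        dv = (g_out_raw - lo_o) / rng_o - orig_o
        val += dv * dv
        if g_out_raw < 0:  # raw nonnegativity of the output coupling
            val += 1e3 * g_out_raw * g_out_raw
        return val

    return obj, unpack


def shortest_path(
    spec: SubcircuitSpec,
    origin_hat: np.ndarray,
    box: NormalizationBox,
    n_starts: int = 20,
    seed: int | None = None,
    factor: float = 1.5,
) -> ShortestPathResult:
    """Multi-start shortest path from ``origin_hat`` (normalized) to S.

    Raises ``ValueError`` if the origin is already allodynic.  Local minima
    are deduplicated at 1e-3 normalized distance and reported when their
    length is at most ``factor`` times the global one.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    origin_hat = np.asarray(origin_hat, dtype=float)
    names = spec.hierarchy
    out_idx = names.index(spec.output_abeta)
    rest_idx = [i for i in range(spec.dim) if i != out_idx]
    g_raw = normalize(origin_hat, box, inverse=True)
    g_dict = spec.coupling_dict(g_raw)
    h, _ = surface_height(spec, g_dict)
    if g_dict[spec.output_abeta] > h + 1e-9:  # strictly above: no path
        raise ValueError("origin is already allodynic; no path to compute")

    obj, unpack = _surface_objective(spec, box, origin_hat, out_idx, rest_idx)
    f0, f1 = spec.f_range
    # raw nonnegativity of the reduced couplings via normalized lower bounds;
    # surface points may leave the unit cube upward, so allow headroom
    lo_b = -box.lo[rest_idx] / box.ranges[rest_idx]
    bounds = [(float(l), 2.5) for l in lo_b] + [(f0, f1)]

    rng = np.random.default_rng(seed)
    starts = [np.concatenate([origin_hat[rest_idx], [0.5 * (f0 + f1)]])]
    for _ in range(n_starts - 1):
        z = np.array([rng.uniform(max(l, -0.25), 1.25) for l, _ in bounds[:-1]]
                     + [rng.uniform(f0, f1)])
        starts.append(z)

    sols = []
    for z0 in starts:
        res = minimize(obj, z0, method="L-BFGS-B", bounds=bounds,
                       options={"ftol": 1e-14, "gtol": 1e-10, "maxiter": 500})
        if not np.isfinite(res.fun):
            continue
        g_rest_hat, raw_rest, g_out_raw = unpack(res.x)
        if g_out_raw < -1e-9:
            continue
        sols.append((float(res.fun), res.x, bool(res.success)))
    n_conv = sum(s[2] for s in sols)
    if not sols:
        raise RuntimeError("no optimizer start converged to the surface")

    def to_surface_point(z):
        g_rest_hat, raw_rest, g_out_raw = unpack(z)
        raw = np.empty(spec.dim)
        raw[rest_idx] = raw_rest
        raw[out_idx] = max(g_out_raw, 0.0)
        return SurfacePoint(
            raw=raw,
            normalized=normalize(raw, box),
            f_nearest=float(z[-1]),
            residual=abs(raw[out_idx] - g_out_raw),
        )

    # deduplicate by location on the surface, keep best length per site
    sols.sort(key=lambda s: s[0])
    unique: list[tuple[float, np.ndarray, np.ndarray]] = []
    for fun, z, _ in sols:
        sp_norm = to_surface_point(z).normalized
        if all(np.linalg.norm(sp_norm - u[2]) >= 1e-3 for u in unique):
            unique.append((fun, z, sp_norm))
    # deterministic tie-breaking among near-equal minima
    unique.sort(key=lambda s: (round(s[0], 12), s[1][-1], tuple(s[1][:-1])))
    best_fun, best_z, _ = unique[0]
    best_sp = to_surface_point(best_z)
    g_len = float(np.sqrt(best_fun))
    locs, lens = [], []
    for fun, z, _ in unique[1:]:
        length = float(np.sqrt(fun))
        if length <= factor * g_len:
            locs.append(to_surface_point(z))
            lens.append(length)
    return ShortestPathResult(
        origin=origin_hat,
        surface_point=best_sp,
        displacement=best_sp.normalized - origin_hat,
        length=g_len,
        local_minima=locs,
        local_lengths=lens,
        factor=factor,
        n_starts=len(starts),
        n_converged=n_conv,
    )


def shortest_paths(
    spec: SubcircuitSpec,
    sample_hat: np.ndarray,
    box: NormalizationBox,
    n_starts: int = 20,
    seed: int | None = None,
    factor: float = 1.5,
) -> list[ShortestPathResult]:
    """Shortest paths for every row of a normalized sample (seeded per row)."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(sample_hat))
    return [
        shortest_path(spec, row, box, n_starts=n_starts,
                      seed=int(child.generate_state(1)[0] % (2 ** 31)),
                      factor=factor)
        for row, child in zip(sample_hat, children)
    ]


def paths_to_frame(spec: SubcircuitSpec, paths) -> pd.DataFrame:
    """Tidy per-point export of shortest-path results."""
    names = spec.hierarchy
    rows = []
    for p in paths:
        row = {f"origin_{nm}": v for nm, v in zip(names, p.origin)}
        row.update({f"surface_{nm}": v
                    for nm, v in zip(names, p.surface_point.normalized)})
        row.update({f"d_{nm}": v for nm, v in zip(names, p.displacement)})
        row["length"] = p.length
        row["f_nearest"] = p.surface_point.f_nearest
        row["n_local_minima"] = len(p.local_minima)
        rows.append(row)
    return pd.DataFrame(rows)
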
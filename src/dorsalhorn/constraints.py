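"""Healthy-behavior constraints and the allowable parameter space (APS).

Healthy dorsal-horn behavior is encoded as inequalities on steady-state
population voltages that must hold across a whole range of Abeta input rates
(10-20 Hz for typical innocuous touch, (0, 10] Hz for weak input):

* inhibitory populations fire but stay below a voltage ceiling;
* the output excitatory population is net-inhibited (pain inhibition) and
  stays silent, within biological voltage bounds;
* ablating an inhibitory population unmasks excitatory firing, reproducing
  interneuron-silencing experiments.

Rewriting each voltage inequality as a bound on one coupling strength turns
the APS into a hierarchical system: the feasible interval of each coupling
depends only on couplings earlier in the hierarchy, with the interval
endpoints given by minima/maxima over the stimulus range of smooth
tanh-based expressions.  Interior extrema of two expression families have
closed forms through the 0 and -1 branches of the Lambert-W function; the
rest are found numerically (coarse grid plus bounded refinement).

Two independent routes to feasibility coexist on purpose:
``check_feasible`` brute-forces the voltage conditions on a stimulus grid
(the ground-truth oracle) while ``analytic_member`` walks the hierarchical
intervals; the test suite holds them against each other.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import lambertw

from .circuits import SubcircuitSpec, steady_state
from .populations import INHIBITORY, PopulationParams

__all__ = [
    "BehaviorCondition",
    "FeasibilityResult",
    "LambertSubproblem",
    "NormalizationBox",
    "conditions_for",
    "check_feasible",
    "lambert_extrema",
    "extremize_over_stimulus",
    "analytic_bounds",
    "analytic_member",
    "presample_hierarchical",
    "normalize",
]

#: lower evaluation edge of the (0, 10] Hz weak-input range; the bound
#: expressions divide by f_Ab, and the f->0 limit is vacuous.
LOW_EPS = 0.1

#: interval-intersection tolerance (mV*s); intervals narrower than this are
#: declared empty.
TOL = 1e-12


# --------------------------------------------------------------------------
# behavior conditions and the brute-force feasibility oracle
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BehaviorCondition:
    """One steady-state voltage inequality over a stimulus range.

    ``direction`` "le" means V_target <= bound, "ge" means V_target >= bound;
    ``bound`` names a :class:`PopulationParams` voltage attribute;
    ``range_kind`` is "stim" for the typical [10, 20] Hz range or "low" for
    the weak-input (0, 10] Hz range.  ``quantifier`` is "all" for conditions
    that must hold across the whole range (healthy behavior), "any" for
    conditions holding at some rate in the range, and "at_fmin" for the
    ablation-induced-allodynia conditions of the static circuit, which
    require the unmasked excitatory population to cross threshold already at
    the weakest typical stimulus rate (for the simple and dynamic circuits
    the threshold expressions are monotone enough that the printed
    whole-range conditions are kept as such).
    """

    label: str
    ablated: frozenset[str]
    target: str
    direction: str
    bound: str
    range_kind: str = "stim"
    quantifier: str = "all"


def _cond(label, ablated, target, direction, bound, range_kind="stim",
          quantifier="all"):
    return BehaviorCondition(label, frozenset(ablated), target, direction,
                             bound, range_kind, quantifier)


_REGISTRY: dict[str, tuple[BehaviorCondition, ...]] = {
    "simple": (
        _cond("I upper bound", (), "I", "le", "V_max"),
        _cond("I fires", (), "I", "ge", "V_thr"),
        _cond("pain inhibition", (), "E", "le", "V_rest"),
        _cond("E silent at low input", (), "E", "le", "V_thr", "low"),
        _cond("E lower bound", (), "E", "ge", "V_min"),
        _cond("E upper bound (I abl)", ("I",), "E", "le", "V_max"),
        _cond("E fires (I abl)", ("I",), "E", "ge", "V_thr"),
    ),
    "static": (
        _cond("I1 upper bound", (), "I1", "le", "V_max"),
        _cond("I1 fires", (), "I1", "ge", "V_thr"),
        _cond("I2 upper bound", (), "I2", "le", "V_max"),
        _cond("I2 fires", (), "I2", "ge", "V_thr"),
        _cond("pain inhibition", (), "E", "le", "V_rest"),
        _cond("E silent at low input", (), "E", "le", "V_thr", "low"),
        _cond("E lower bound", (), "E", "ge", "V_min"),
        _cond("E fires (I1 abl)", ("I1",), "E", "ge", "V_thr",
              quantifier="at_fmin"),
        _cond("E upper bound (I1 abl)", ("I1",), "E", "le", "V_max"),
        _cond("E fires (I2 abl)", ("I2",), "E", "ge", "V_thr",
              quantifier="at_fmin"),
        _cond("E upper bound (I2 abl)", ("I2",), "E", "le", "V_max"),
    ),
    "dynamic": (
        _cond("I1 upper bound", (), "I1", "le", "V_max"),
        _cond("I1 fires", (), "I1", "ge", "V_thr"),
        _cond("I2 upper bound", (), "I2", "le", "V_max"),
        _cond("I2 fires", (), "I2", "ge", "V_thr"),
        _cond("pain inhibition (E2)", (), "E2", "le", "V_rest"),
        _cond("E2 silent at low input", (), "E2", "le", "V_thr", "low"),
        _cond("pain inhibition (E1)", (), "E1", "le", "V_rest"),
        _cond("E1 lower bound", (), "E1", "ge", "V_min"),
        _cond("E2 lower bound (E1 abl)", ("E1",), "E2", "ge", "V_min"),
        _cond("E1 fires (I1 abl)", ("I1",), "E1", "ge", "V_thr"),
        _cond("E1 upper bound (I1 abl)", ("I1",), "E1", "le", "V_max"),
        _cond("E2 upper bound (I1 abl)", ("I1",), "E2", "le", "V_max"),
        _cond("E2 fires (I1 abl)", ("I1",), "E2", "ge", "V_thr"),
        _cond("E2 upper bound (I2 abl)", ("I2",), "E2", "le", "V_max"),
        _cond("E2 fires (I2 abl)", ("I2",), "E2", "ge", "V_thr"),
    ),
}


def register_conditions(name: str, conditions: Sequence[BehaviorCondition]) -> None:
    """Attach a condition registry to a custom circuit name."""
    _REGISTRY[name] = tuple(conditions)


def conditions_for(spec: SubcircuitSpec) -> tuple[BehaviorCondition, ...]:
    try:
        return _REGISTRY[spec.name]
    except KeyError:
        raise KeyError(f"no behavior conditions registered for {spec.name!r}")


@dataclass
class FeasibilityResult:
    ok: bool
    violated: list[str]

    def __bool__(self) -> bool:
        return self.ok


def _condition_grid(spec: SubcircuitSpec, cond: BehaviorCondition,
                    n_grid: int) -> np.ndarray:
    if cond.quantifier == "at_fmin":
        return np.array([spec.f_range[0]])
    if cond.range_kind == "stim":
        return np.linspace(spec.f_range[0], spec.f_range[1], n_grid)
    return np.linspace(max(LOW_EPS, spec.low_range[0] + LOW_EPS / 2),
                       spec.low_range[1], n_grid)


def _batch_voltages(spec, G, f, ablated):
    """Steady voltages for a batch of coupling vectors G (n, d) on grid f."""
    col = {name: i for i, name in enumerate(spec.hierarchy)}
    volt: dict[str, np.ndarray] = {}
    rate: dict[str, np.ndarray] = {}
    n = G.shape[0]
    for pid in spec.topological_order():
        pop = spec.params(pid)
        if pid in ablated:
            volt[pid] = np.full((n, len(f)), pop.V_rest)
            rate[pid] = np.zeros((n, len(f)))
            continue
        V = np.full((n, len(f)), pop.V_rest)
        for c in spec.incoming(pid):
            drive = f[None, :] if c.source == "Abeta" else rate[c.source]
            V = V + c.sign * G[:, col[c.name]][:, None] * drive
        volt[pid] = V
        # inline activation: the per-call finiteness guard is wasteful here
        rate[pid] = 0.5 * pop.m * (1.0 + np.tanh((V - pop.beta) / pop.alpha))
    return volt


def check_feasible_batch(
    spec: SubcircuitSpec, G: np.ndarray, n_grid: int = 200
) -> np.ndarray:
    """Vectorized :func:`check_feasible` over rows of ``G`` (n, d).

    Returns a boolean mask; used by the rejection sampler and cover probes
    where per-point condition reports are not needed.
    """
    G = np.atleast_2d(np.asarray(G, dtype=float))
    ok = np.ones(G.shape[0], dtype=bool)
    cache: dict[tuple, dict] = {}
    for cond in conditions_for(spec):
        key = (cond.ablated, cond.range_kind, cond.quantifier == "at_fmin")
        if key not in cache:
            f = _condition_grid(spec, cond, n_grid)
            cache[key] = _batch_voltages(spec, G, f, cond.ablated)
        V = cache[key][cond.target]
        bound = getattr(spec.params(cond.target), cond.bound)
        hold = V <= bound + 1e-9 if cond.direction == "le" else V >= bound - 1e-9
        ok &= hold.any(axis=1) if cond.quantifier == "any" else hold.all(axis=1)
    return ok


def check_feasible(
    spec: SubcircuitSpec, g: Mapping[str, float], n_grid: int = 200
) -> FeasibilityResult:
    """Brute-force oracle: evaluate every condition on a stimulus grid.

    Ground truth for the analytic bounds; a point is feasible iff every
    condition holds at every grid point.
    """
    if n_grid < 50:
        raise ValueError("n_grid must be >= 50")
    if isinstance(g, np.ndarray) or not isinstance(g, Mapping):
        g = spec.coupling_dict(np.asarray(g, dtype=float))
    violated: list[str] = []
    cache: dict[tuple, dict] = {}
    for cond in conditions_for(spec):
        key = (cond.ablated, cond.range_kind, cond.quantifier == "at_fmin")
        if key not in cache:
            f = _condition_grid(spec, cond, n_grid)
            cache[key] = steady_state(spec, g, f, cond.ablated).voltage
        V = cache[key][cond.target]
        bound = getattr(spec.params(cond.target), cond.bound)
        agg = np.any if cond.quantifier == "any" else np.all
        ok = agg(V <= bound + 1e-9) if cond.direction == "le" else \
            agg(V >= bound - 1e-9)
        if not ok:
            violated.append(cond.label)
    return FeasibilityResult(not violated, violated)


# --------------------------------------------------------------------------
# Lambert-W closed forms for interior stimulus extrema
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LambertSubproblem:
    """One min/max-over-stimulus subproblem with tanh structure.

    Two families appear in the coupling bounds.  With
    ``r(f) = 0.5 m (1 + tanh((V_rest + g_inner f - beta)/alpha))`` the rate
    of a population driven only by Abeta input:

    * ``kind="rate_over_f"``:     objective ``(g_outer * r(f) + C) / f``
      (pain-inhibition style rows); closed form requires ``C == 0``.
    * ``kind="affine_over_rate"``: objective ``(g_outer * f + C) / r(f)``
      (ablation-row style); closed form for any ``C``.

    In the substitution ``x = g_inner f / alpha`` the numerator of the first
    family reads ``a (1 + tanh(x - b)) + C`` with ``a = 0.5 g_outer m`` and
    ``b = (beta - V_rest)/alpha``.
    """

    g_inner: float
    g_outer: float
    C: float
    interval: tuple[float, float]
    pop: PopulationParams = INHIBITORY
    kind: str = "rate_over_f"

    @property
    def a(self) -> float:
        return 0.5 * self.g_outer * self.pop.m

    @property
    def b(self) -> float:
        return (self.pop.beta - self.pop.V_rest) / self.pop.alpha

    @property
    def c(self) -> float:
        return self.C

    def rate(self, f):
        return self.pop.rate(self.pop.V_rest + self.g_inner * np.asarray(f, float))

    def objective(self, f):
        f = np.asarray(f, dtype=float)
        if self.kind == "rate_over_f":
            return (self.g_outer * self.rate(f) + self.C) / f
        return (self.g_outer * f + self.C) / self.rate(f)


def lambert_extrema(sub: LambertSubproblem) -> list[float]:
    """Interior critical stimulus rates of ``sub.objective`` (Hz).

    Stationary points of both families reduce, after the substitution
    ``x = g_inner f / alpha``, to ``(2s - 1) e^{-(2s-1)} = e^{1 - 2b - 2k}``
    with ``s = x + k``, where the offset ``k`` is 0 for the pure
    rate-over-stimulus family and ``C g_inner / (g_outer alpha)`` for the
    affine-over-rate family.  Hence ``s = (1 - W_{0,-1}(-e^{1-2b-2k}))/2``.
    Roots are filtered to the real axis and the stimulus interval; an empty
    list is a valid result (extrema then sit at the endpoints).
    """
    if sub.kind == "rate_over_f":
        if sub.C != 0.0:
            raise ValueError("closed form requires C == 0 for rate_over_f")
        kappa = 0.0
    elif sub.kind == "affine_over_rate":
        if sub.g_outer == 0.0:
            return []
        kappa = sub.C * sub.g_inner / (sub.g_outer * sub.pop.alpha)
    else:
        raise ValueError(f"unknown kind {sub.kind!r}")
    if sub.g_inner <= 0:
        return []
    arg = -np.exp(1.0 - 2.0 * sub.b - 2.0 * kappa)
    if arg < -np.exp(-1.0):  # outside the domain of the real branches
        return []
    roots: list[float] = []
    lo, hi = sub.interval
    for branch in (0, -1):
        w = lambertw(arg, branch)
        if abs(w.imag) > 1e-12:
            continue
        s = 0.5 * (1.0 - w.real)
        x = s - kappa
        f = sub.pop.alpha * x / sub.g_inner
        if lo < f < hi and np.isfinite(f):
            roots.append(float(f))
    return sorted(roots)


# --------------------------------------------------------------------------
# generic extremization over the stimulus range
# --------------------------------------------------------------------------

def extremize_over_stimulus(
    objective: Callable[[np.ndarray], np.ndarray],
    interval: tuple[float, float],
    mode: str,
    criticals: Sequence[float] | None = None,
    n_coarse: int = 201,
    refine: bool = True,
) -> tuple[float, float]:
    """Extremal value and argument of ``objective`` on ``interval``.

    If ``criticals`` is given (Lambert closed form), the candidate set is
    endpoints + criticals.  Otherwise a coarse grid locates bracketed local
    extrema which are polished with bounded scalar minimization.  Ties go to
    the leftmost argument.
    """
    lo, hi = float(interval[0]), float(interval[1])
    if not lo < hi:
        if lo == hi:
            return float(objective(np.array([lo]))[0]), lo
        raise ValueError("empty stimulus interval")
    if mode not in ("min", "max"):
        raise ValueError("mode must be 'min' or 'max'")
    sign = 1.0 if mode == "min" else -1.0

    if criticals is not None:
        cands = np.array([lo, hi] + [c for c in criticals if lo < c < hi])
    else:
        grid = np.linspace(lo, hi, n_coarse)
        vals = sign * np.asarray(objective(grid), dtype=float)
        cands = [lo, hi]
        if refine:
            interior = np.where(
                (vals[1:-1] <= vals[:-2]) & (vals[1:-1] <= vals[2:])
            )[0] + 1
            for i in interior:
                res = minimize_scalar(
                    lambda f: sign * float(objective(np.array([f]))[0]),
                    bounds=(grid[i - 1], grid[i + 1]),
                    method="bounded",
                    options={"xatol": 1e-10},
                )
                cands.append(float(res.x))
        else:
            cands.append(float(grid[np.argmin(vals)]))
        cands = np.array(cands)
    cvals = sign * np.asarray(objective(cands), dtype=float)
    best = np.argmin(cvals)
    # deterministic tie-break: smallest argument among near-equal values
    near = np.where(cvals <= cvals[best] + 1e-12 * max(1.0, abs(cvals[best])))[0]
    best = near[np.argmin(cands[near])]
    return float(sign * cvals[best]), float(cands[best])


def _vmin(fn, interval, criticals=None):
    return extremize_over_stimulus(fn, interval, "min", criticals)[0]


def _vmax(fn, interval, criticals=None):
    return extremize_over_stimulus(fn, interval, "max", criticals)[0]


# --------------------------------------------------------------------------
# hierarchical analytic bounds per circuit
# --------------------------------------------------------------------------

def _abeta_rate(pop: PopulationParams, g_a: float):
    """Rate-vs-stimulus function for a population driven only by Abeta."""
    def r(f):
        return pop.rate(pop.V_rest + g_a * np.asarray(f, dtype=float))
    return r


def _dv(pop: PopulationParams) -> dict[str, float]:
    return {
        "thr": pop.V_thr - pop.V_rest,     # drive needed to reach threshold
        "max": pop.V_max - pop.V_rest,     # headroom to the ceiling
        "min": pop.V_rest - pop.V_min,     # room down to the floor
        "span": pop.V_max - pop.V_min,
    }


def _intersect(*intervals):
    lo = max(iv[0] for iv in intervals)
    hi = min(iv[1] for iv in intervals)
    if hi - lo < TOL:
        return None
    return (lo, hi)


def _simple_interval(spec, level, vals):
    stim = spec.f_range
    low = (LOW_EPS, spec.low_range[1])
    I, E = spec.params("I"), spec.params("E")
    dI, dE = _dv(I), _dv(E)
    f0, f1 = stim
    if level == 0:  # g_AbI: I fires at f0, stays under ceiling at f1
        return (dI["thr"] / f0, dI["max"] / f1)
    g_ai = vals[0]
    rI = _abeta_rate(I, g_ai)
    if level == 1:  # g_IE: necessary bracket; exactness lands on g_AbE
        # lower edge: pain inhibition at f_min against the ablation-fires
        # floor requires g_IE * r_I(f_min) >= dV_thr
        return _intersect(((dE["thr"] / rI(np.array([f0]))[0],
                            dE["span"] / rI(np.array([f1]))[0])))
    g_ie = vals[1]
    # g_AbE: every E-population row, exact
    lam = lambert_extrema(LambertSubproblem(g_ai, g_ie, 0.0, stim))
    ub_pi = _vmin(lambda f: g_ie * rI(f) / f, stim, criticals=lam)
    ub_low = _vmin(lambda f: (g_ie * rI(f) + dE["thr"]) / f, low)
    lb_floor = _vmax(lambda f: (g_ie * rI(f) - dE["min"]) / f, stim)
    return _intersect(
        (dE["thr"] / f0, dE["max"] / f1),
        (0.0, ub_pi),
        (0.0, ub_low),
        (lb_floor, np.inf),
        (0.0, np.inf),
    )


def _static_completion_scan(spec, g_a1, g_a2, g_ae=None,
                            nf=128, n_ae=48, n_1e=32):
    """Scan for assignments with a feasible completion (static circuit).

    With ``g_ae=None``, returns the [min, max] span of g_AbE candidates for
    which some (g_I1E, g_I2E) completion exists; otherwise the span of
    g_I1E candidates admitting a g_I2E.  Grid-based outer approximation:
    never discards a truly completable candidate (holes are handled by the
    presampler's restart), may admit borderline ones.
    """
    E = spec.params("E")
    dE = _dv(E)
    f0, f1 = spec.f_range
    fs = np.linspace(f0, f1, nf)
    fl = np.linspace(LOW_EPS, spec.low_range[1], nf)
    r1s = _abeta_rate(spec.params("I1"), g_a1)(fs)
    r2s = _abeta_rate(spec.params("I2"), g_a2)(fs)
    r1l = _abeta_rate(spec.params("I1"), g_a1)(fl)
    r2l = _abeta_rate(spec.params("I2"), g_a2)(fl)
    cap1 = dE["span"] / r1s[-1]
    cap2 = dE["span"] / r2s[-1]

    if g_ae is None:
        hi_nec = min(
            np.min((cap1 * r1s + cap2 * r2s) / fs),
            np.min((cap1 * r1l + cap2 * r2l + dE["thr"]) / fl),
            np.min((dE["max"] + cap2 * r2s) / fs),
            np.min((dE["max"] + cap1 * r1s) / fs),
        )
        # pain inhibition at f_min against the two f_min fires caps forces
        # g_AbE >= 2 dV_thr / f_min (= 7.02 mV*s)
        lo_nec = 2.0 * dE["thr"] / f0
        if hi_nec - lo_nec < TOL:
            return None
        A = np.linspace(lo_nec, hi_nec, n_ae)[:, None]          # (na, 1)
    else:
        A = np.array([[float(g_ae)]])
    # exact-row interval for g_I1E per g_AbE candidate (I2-ablation rows);
    # the fires row binds at f_min only
    lo1 = np.maximum(np.max((A * fs - dE["max"]) / r1s, axis=1),
                     dE["thr"] / r1s[0])
    hi1 = np.minimum((A[:, 0] * f0 - dE["thr"]) / r1s[0],
                     np.min((A * fs + dE["min"]) / r1s, axis=1))
    lo1 = np.maximum(lo1, 0.0)
    open1 = hi1 - lo1 > TOL
    if not open1.any():
        return None
    frac = np.linspace(0.0, 1.0, n_1e)
    G1 = lo1[:, None] + frac * (hi1 - lo1)[:, None]             # (na, n1)
    A3, G13 = A[:, :, None], G1[:, :, None]                     # broadcast vs f
    lo2 = np.max((A3 * fs - G13 * r1s) / r2s, axis=2)           # pain inhibition
    lo2 = np.maximum(lo2, np.max((A3 * fs - dE["max"]) / r2s, axis=2))  # I1-abl ceiling
    lo2 = np.maximum(lo2, np.max((A3 * fl - dE["thr"] - G13 * r1l) / r2l, axis=2))
    lo2 = np.maximum(lo2, 0.0)
    hi2 = np.min((A3 * fs + dE["min"] - G13 * r1s) / r2s, axis=2)  # voltage floor
    hi2 = np.minimum(hi2, (A * f0 - dE["thr"]) / r2s[0])  # I1-abl fires at f_min
    ok = open1 & np.any(hi2 - lo2 > TOL, axis=1)
    if not ok.any():
        return None
    if g_ae is None:
        vals = A[ok, 0]
        return (float(vals.min()), float(vals.max()))
    g1_ok = G1[0][(hi2 - lo2)[0] > TOL]
    return (float(g1_ok.min()), float(g1_ok.max()))


def _static_interval(spec, level, vals, scan=False):
    stim = spec.f_range
    low = (LOW_EPS, spec.low_range[1])
    E = spec.params("E")
    dI, dE = _dv(spec.params("I1")), _dv(E)
    f0, f1 = stim
    if level in (0, 1):  # g_AbI1, g_AbI2
        return (dI["thr"] / f0, dI["max"] / f1)
    g_a1, g_a2 = vals[0], vals[1]
    r1 = _abeta_rate(spec.params("I1"), g_a1)
    r2 = _abeta_rate(spec.params("I2"), g_a2)
    # parameter-free caps on the inhibitory->E couplings (necessary)
    cap1 = dE["span"] / r1(np.array([f1]))[0]
    cap2 = dE["span"] / r2(np.array([f1]))[0]
    if level == 2:  # g_AbE: necessary bracket from relaxed rows
        if scan:
            return _static_completion_scan(spec, g_a1, g_a2)
        ub_pi = _vmin(lambda f: (cap1 * r1(f) + cap2 * r2(f)) / f, stim)
        ub_low = _vmin(lambda f: (cap1 * r1(f) + cap2 * r2(f) + dE["thr"]) / f, low)
        ub_ab1 = _vmin(lambda f: (dE["max"] + cap2 * r2(f)) / f, stim)
        ub_ab2 = _vmin(lambda f: (dE["max"] + cap1 * r1(f)) / f, stim)
        return _intersect((2.0 * dE["thr"] / f0, np.inf),
                          (0.0, min(ub_pi, ub_low, ub_ab1, ub_ab2)))
    g_ae = vals[2]

    def abl_rows(r, g_a):
        """Exact I-ablation rows bounding the OTHER inhibitory coupling.

        The ceiling row holds for all f (lower bound via the Lambert-form
        max over f); the fires row binds at f_min.
        """
        lam_lo = lambert_extrema(LambertSubproblem(
            g_a, g_ae, -dE["max"], stim, kind="affine_over_rate"))
        hi = (g_ae * f0 - dE["thr"]) / r(np.array([f0]))[0]
        lo = _vmax(lambda f: (g_ae * f - dE["max"]) / r(f), stim, criticals=lam_lo)
        return lo, hi

    if level == 3:  # g_I1E: exact I2-ablation rows + necessary relaxations
        lo_x, hi_x = abl_rows(r1, g_a1)  # I2 ablated -> rows in f_I1
        lo_pi = _vmax(lambda f: (g_ae * f - cap2 * r2(f)) / r1(f), stim)
        lo_low = _vmax(lambda f: (g_ae * f - dE["thr"] - cap2 * r2(f)) / r1(f), low)
        lo_thr = dE["thr"] / r1(np.array([f0]))[0]
        hi_floor = _vmin(lambda f: (g_ae * f + dE["min"]) / r1(f), stim)
        iv = _intersect((lo_x, hi_x),
                        (max(lo_pi, lo_low, lo_thr, 0.0),
                         min(hi_floor, cap1)))
        if scan and iv is not None:
            narrowed = _static_completion_scan(spec, g_a1, g_a2, g_ae=g_ae)
            iv = None if narrowed is None else _intersect(iv, narrowed)
        return iv
    g_1e = vals[3]
    # g_I2E: every remaining row, exact
    lo_x, hi_x = abl_rows(r2, g_a2)  # I1 ablated -> rows in f_I2
    lo_pi = _vmax(lambda f: (g_ae * f - g_1e * r1(f)) / r2(f), stim)
    lo_low = _vmax(lambda f: (g_ae * f - dE["thr"] - g_1e * r1(f)) / r2(f), low)
    hi_floor = _vmin(lambda f: (g_ae * f + dE["min"] - g_1e * r1(f)) / r2(f), stim)
    return _intersect((lo_x, hi_x),
                      (max(lo_pi, lo_low, 0.0), hi_floor))


def _dynamic_e1_rate(spec, g_a1, g_1e1, g_ae1):
    """Control-condition E1 rate vs stimulus (inhibited by I1)."""
    E1 = spec.params("E1")
    r1 = _abeta_rate(spec.params("I1"), g_a1)

    def rE1(f):
        f = np.asarray(f, dtype=float)
        return E1.rate(E1.V_rest + g_ae1 * f - g_1e1 * r1(f))

    return rE1


def _dynamic_abe2_interval_grid(spec, vals, fs, fl):
    """Grid-evaluated g_AbE2 interval for the dynamic circuit.

    All rows are affine in the couplings, so a coarse stimulus grid gives an
    outer approximation used by the level-5 candidate scan; the final draw
    recomputes the interval with refined extremization.
    """
    g_a1, g_a2, g_1e1, g_ae1, g_e12, g_2e2 = vals[:6]
    dE = _dv(spec.params("E2"))
    r2 = _abeta_rate(spec.params("I2"), g_a2)
    rE1 = _dynamic_e1_rate(spec, g_a1, g_1e1, g_ae1)
    rE1_abl = _abeta_rate(spec.params("E1"), g_ae1)  # I1 ablated
    hi = min(
        np.min((g_2e2 * r2(fl) - g_e12 * rE1(fl) + dE["thr"]) / fl),  # low input
        np.min((g_2e2 * r2(fs) - g_e12 * rE1(fs)) / fs),              # pain inhib
        np.min((g_2e2 * r2(fs) - g_e12 * rE1_abl(fs) + dE["max"]) / fs),  # I1 abl UB
        np.min((dE["max"] - g_e12 * rE1(fs)) / fs),                   # I2 abl UB
    )
    lo = max(
        np.max((g_2e2 * r2(fs) - dE["min"]) / fs),                    # E1 abl floor
        np.max((g_2e2 * r2(fs) - g_e12 * rE1_abl(fs) + dE["thr"]) / fs),  # I1 abl fires
        np.max((dE["thr"] - g_e12 * rE1(fs)) / fs),                   # I2 abl fires
        0.0,
    )
    return float(lo), float(hi)


def _dynamic_interval(spec, level, vals, scan=False):
    stim = spec.f_range
    low = (LOW_EPS, spec.low_range[1])
    dI = _dv(spec.params("I1"))
    dE = _dv(spec.params("E1"))
    f0, f1 = stim
    if level in (0, 1):  # g_AbI1, g_AbI2
        return (dI["thr"] / f0, dI["max"] / f1)
    g_a1, g_a2 = vals[0], vals[1]
    r1 = _abeta_rate(spec.params("I1"), g_a1)
    r2 = _abeta_rate(spec.params("I2"), g_a2)
    if level == 2:  # g_I1E1: necessary bracket, same role as simple g_IE
        return _intersect(((dE["thr"] / r1(np.array([f0]))[0],
                            dE["span"] / r1(np.array([f1]))[0])))
    g_1e1 = vals[2]
    if level == 3:  # g_AbE1: exact E1 rows (simple circuit minus low-input row)
        lam = lambert_extrema(LambertSubproblem(g_a1, g_1e1, 0.0, stim))
        ub_pi = _vmin(lambda f: g_1e1 * r1(f) / f, stim, criticals=lam)
        lb_floor = _vmax(lambda f: (g_1e1 * r1(f) - dE["min"]) / f, stim)
        return _intersect((dE["thr"] / f0, dE["max"] / f1),
                          (max(lb_floor, 0.0), ub_pi))
    g_ae1 = vals[3]
    rE1_abl = _abeta_rate(spec.params("E1"), g_ae1)
    # necessary cap on g_I2E2: floor row relaxed with the loosest g_AbE2
    # (whose own ceiling row caps it at dE.max / f1)
    cap_2e2 = _vmin(lambda f: (dE["max"] / f1 * f + dE["min"]) / r2(f), stim)
    if level == 4:  # g_E1E2: necessary cap from the I1-ablation ceiling row
        cap = _vmin(lambda f: (dE["max"] + cap_2e2 * r2(f)) / rE1_abl(f), stim)
        return _intersect((0.0, cap))
    if level == 5:  # g_I2E2
        if not scan:
            return _intersect((0.0, cap_2e2))
        # narrow by scanning candidates for which the g_AbE2 interval opens
        fs = np.linspace(f0, f1, 160)
        fl = np.linspace(LOW_EPS, spec.low_range[1], 160)
        cands = np.linspace(0.0, cap_2e2, 65)
        ok = np.zeros(len(cands), dtype=bool)
        for i, c in enumerate(cands):
            lo, hi = _dynamic_abe2_interval_grid(spec, list(vals[:5]) + [c], fs, fl)
            ok[i] = hi - lo > TOL
        if not ok.any():
            return None
        return (float(cands[ok].min()), float(cands[ok].max()))
    # level 6, g_AbE2: every remaining row, exact
    g_e12, g_2e2 = vals[4], vals[5]
    rE1 = _dynamic_e1_rate(spec, g_a1, g_1e1, g_ae1)
    dE2 = _dv(spec.params("E2"))
    hi = min(
        _vmin(lambda f: (g_2e2 * r2(f) - g_e12 * rE1(f) + dE2["thr"]) / f, low),
        _vmin(lambda f: (g_2e2 * r2(f) - g_e12 * rE1(f)) / f, stim),
        _vmin(lambda f: (g_2e2 * r2(f) - g_e12 * rE1_abl(f) + dE2["max"]) / f, stim),
        _vmin(lambda f: (dE2["max"] - g_e12 * rE1(f)) / f, stim),
    )
    lo = max(
        _vmax(lambda f: (g_2e2 * r2(f) - dE2["min"]) / f, stim),
        _vmax(lambda f: (g_2e2 * r2(f) - g_e12 * rE1_abl(f) + dE2["thr"]) / f, stim),
        _vmax(lambda f: (dE2["thr"] - g_e12 * rE1(f)) / f, stim),
        0.0,
    )
    return _intersect((lo, hi))


_INTERVAL_FNS = {
    "simple": _simple_interval,
    "static": _static_interval,
    "dynamic": _dynamic_interval,
}


def analytic_bounds(
    spec: SubcircuitSpec,
    assigned: Mapping[str, float],
    for_sampling: bool = False,
) -> tuple[str, tuple[float, float] | None]:
    """Feasible interval for the next coupling in hierarchy order.

    ``assigned`` must contain exactly the couplings below the requested one
    in the hierarchy.  Returns ``(name, (lo, hi))`` or ``(name, None)`` when
    the partial assignment admits no completion at this level.  With
    ``for_sampling`` the dynamic circuit narrows its second-to-last level by
    a candidate scan (slower, but lifts the presampler's acceptance rate).
    """
    level = len(assigned)
    if level >= spec.dim:
        raise ValueError("all couplings already assigned")
    for k in spec.hierarchy[:level]:
        if k not in assigned:
            raise ValueError(f"parameters assigned out of hierarchy order: missing {k}")
    name = spec.hierarchy[level]
    vals = [float(assigned[k]) for k in spec.hierarchy[:level]]
    fn = _INTERVAL_FNS.get(spec.name)
    if fn is None:
        raise KeyError(f"no analytic bounds registered for circuit {spec.name!r}")
    if spec.name in ("static", "dynamic"):
        iv = fn(spec, level, vals, scan=for_sampling)
    else:
        iv = fn(spec, level, vals)
    if iv is not None:
        iv = (max(iv[0], 0.0), iv[1])
        if iv[1] - iv[0] < TOL:
            iv = None
    return name, iv


def analytic_member(spec: SubcircuitSpec, g) -> bool:
    """Membership via the hierarchical intervals (no stimulus grid)."""
    if isinstance(g, Mapping):
        g = spec.coupling_array(g)
    g = np.asarray(g, dtype=float)
    assigned: dict[str, float] = {}
    for i, name in enumerate(spec.hierarchy):
        _, iv = analytic_bounds(spec, assigned)
        if iv is None or not (iv[0] - 1e-9 <= g[i] <= iv[1] + 1e-9):
            return False
        assigned[name] = float(g[i])
    return True


# --------------------------------------------------------------------------
# hierarchical presampling and normalization
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NormalizationBox:
    """Per-coupling [g_min, g_max] bounding box of an APS presample."""

    names: tuple[str, ...]
    lo: np.ndarray
    hi: np.ndarray
    n_presample: int
    seed: int | None

    def __post_init__(self) -> None:
        if np.any(self.hi <= self.lo):
            raise ValueError("degenerate box: g_min must be < g_max")

    @property
    def ranges(self) -> np.ndarray:
        return self.hi - self.lo

    def to_dict(self) -> dict:
        return {
            "names": list(self.names),
            "lo": self.lo.tolist(),
            "hi": self.hi.tolist(),
            "n_presample": self.n_presample,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "NormalizationBox":
        return cls(tuple(d["names"]), np.asarray(d["lo"], float),
                   np.asarray(d["hi"], float), int(d["n_presample"]),
                   d.get("seed"))


def normalize(g, box: NormalizationBox, inverse: bool = False) -> np.ndarray:
    """Affine map to box coordinates, ``(g - lo) / (hi - lo)``, or back."""
    g = np.asarray(g, dtype=float)
    if inverse:
        return box.lo + g * box.ranges
    return (g - box.lo) / box.ranges


def presample_hierarchical(
    spec: SubcircuitSpec,
    n: int = 1000,
    seed: int | None = None,
    retry_factor: int = 100,
) -> tuple[np.ndarray, NormalizationBox]:
    """Draw ``n`` APS points by sequential sampling down the hierarchy.

    Each coupling is drawn uniformly inside its conditional interval; an
    empty interval restarts the draw from the top.  The sample is feasible
    by construction but not spatially uniform; its coordinatewise min/max
    define the normalization box.
    """
    if n < 1000:
        raise ValueError("presample size must be >= 1000")
    rng = np.random.default_rng(seed)
    out = np.empty((n, spec.dim))
    accepted = 0
    attempts = 0
    budget = retry_factor * n
    while accepted < n:
        attempts += 1
        if attempts > budget:
            raise RuntimeError(
                f"presampler found {accepted}/{n} points in {budget} attempts; "
                "the constraint system looks infeasible"
            )
        assigned: dict[str, float] = {}
        for name in spec.hierarchy:
            _, iv = analytic_bounds(spec, assigned, for_sampling=True)
            if iv is None:
                break
            assigned[name] = rng.uniform(iv[0], iv[1])
        else:
            out[accepted] = [assigned[k] for k in spec.hierarchy]
            accepted += 1
    box = NormalizationBox(
        names=spec.hierarchy,
        lo=out.min(axis=0),
        hi=out.max(axis=0),
        n_presample=n,
        seed=seed,
    )
    return out, box
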
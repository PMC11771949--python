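# Methods

## Population model

Each interneuron population is a firing-rate unit: mean voltage `V_x` (mV)
relaxes with time constant `tau_x` toward `V_x,rest` plus the rate-weighted
sum of its inputs, and the mean rate is the static sigmoid
`f_x = 0.5 m_x (1 + tanh((V_x - beta_x)/alpha_x))`.  Default constants
(inhibitory: `m = 80 Hz`, `alpha = 9.3 mV`, `beta = -30 mV`,
`tau = 0.02 s`; excitatory: `m = 50 Hz`, `alpha = 7.9 mV`,
`beta = -17 mV`, `tau = 0.024 s`; both rest at `-60 mV`) reflect fits of
the sigmoid to frequency-voltage measurements in rat dorsal-horn neurons:
tonic-firing lamina I cells for inhibitory populations, delayed-firing
lamina I-II cells for excitatory ones, with `tau_E/tau_I = 1.2`.  Firing
threshold and the biological voltage floor/ceiling are *derived*
quantities, `beta - alpha` and `beta -/+ 12 alpha` (rate fractions ~0.12,
~4e-11 and ~1 - 4e-11 of maximum), so they can never drift out of sync
with the activation parameters.

Couplings `g_yx` carry units of mV*s (a presynaptic rate in Hz times
`g` gives a voltage offset in mV).  They are sometimes quoted in the
literature in V*s; dimensional consistency of the voltage equation in mV
forces mV*s, which is used throughout.

All steady-state analysis uses the closed-form fixed point
`V^ss = V_rest + inputs` evaluated in topological order (the circuits are
feedforward, so no fixed-point iteration is needed).  Time-domain
simulation uses fixed-step RK4 at `dt = 1 ms <= tau/20` with the stimulus
held zero-order; since the Poisson bundle stimulus is itself piecewise
constant per 1-ms bin, the integrator commits no stimulus-interpolation
error.

## Synthetic Abeta input

The stimulus generator emulates a bundle of 300 Abeta fibers, each an
independent Poisson process at 1 Hz background and `f_ab` in [10, 20] Hz
during the stimulus window (0.2-0.7 s by default).  Only per-bin counts
matter to a rate model, so one Poisson draw per bin for the whole bundle
(mean `n_fibers * rate * dt`) replaces event-time simulation; the two are
distributionally identical at the rate readout.  What the generator does
*not* emulate: fiber adaptation, refractoriness, inter-fiber correlation,
and Adelta/C-fiber streams.  Tests passing on this input therefore
certify the pipeline's behavior for idealized stationary afferent drive,
not for structured natural stimuli.

## Healthy-behavior constraints and the APS

Healthy behavior is encoded as steady-state voltage inequalities per
circuit: inhibitory populations fire (`V >= V_thr`) without exceeding
`V_max` across the whole innocuous range [10, 20] Hz; the output
excitatory population is net-inhibited (`V <= V_rest`), bounded below by
`V_min`, and silent (`V <= V_thr`) for weak inputs (0, 10] Hz; and
ablation of an inhibitory population must unmask output firing, mirroring
interneuron-silencing experiments.

Quantifiers are the one genuinely open design point.  Healthy-behavior
conditions must hold for *every* rate in their range.  For the
ablation-allodynia conditions this package uses, per circuit, the weakest
reading that leaves the constraint system satisfiable while preserving the
expected structure of each allowable space:

* simple and dynamic circuits: the threshold-crossing conditions hold for
  all rates in [10, 20] Hz (for the simple circuit this is equivalent to
  requiring crossing at 10 Hz, the expressions being monotone);
* static circuit: crossing is required at the weakest typical rate,
  10 Hz.  The for-all version is provably infeasible here: pain inhibition
  at 10 Hz plus the two ablation caps force near-saturated inhibitory
  rates at 10 Hz, which cannot then grow enough by 20 Hz to keep pain
  inhibition — a race with no winners.  The 10-Hz form yields the expected
  structure: `g_AbE >= 2(V_E,thr - V_E,rest)/f_min = 7.02 mV*s` with a
  narrow admissible band, and an APS in which one inhibitory population is
  strongly driven and the other weakly (the mirror bimodality that the
  two-cluster mechanism split rests on).

Rewriting each voltage inequality as a bound on a single coupling makes
the system hierarchical: parameter k's feasible interval depends only on
parameters earlier in the order (simple: `g_AbI, g_IE, g_AbE`; static:
`g_AbI1, g_AbI2, g_AbE, g_I1E, g_I2E`; dynamic: `g_AbI1, g_AbI2, g_I1E1,
g_AbE1, g_E1E2, g_I2E2, g_AbE2`).  Interval endpoints are minima/maxima
over the stimulus range of smooth tanh expressions.  Two expression
families admit closed-form interior extrema through the Lambert-W
branches `W_0` and `W_-1` (see `constraints.LambertSubproblem`): the
rate-over-stimulus family `g r(f)/f` and the affine-over-rate family
`(G f + K)/r(f)`; all other rows are extremized numerically (201-point
coarse grid, every bracketed interior extremum polished by bounded scalar
minimization to `xatol = 1e-10`).  The brute-force oracle
(`check_feasible`, all conditions on a stimulus grid) is kept as an
independent code path and the two are tested against each other.

Mid-hierarchy parameters whose exact interval is not expressible in closed
form get *necessary* (outer) intervals plus, for sampling only, a
candidate scan that keeps the span of values admitting a feasible
completion; holes are handled by the presampler's restart rule, so
sampled points are exact members while the sampler stays fast.
Intervals narrower than `1e-12 mV*s` count as empty; the presampler
restarts from the top on any empty interval and gives up after `100 n`
attempts.  The weak-input conditions are evaluated on (0.1, 10] Hz: the
bounding expressions divide by the rate, and the limit at 0 is vacuous.

## Normalization and uniform sampling

The per-coupling min/max over a 1000-point hierarchical presample defines
the normalization box; normalized couplings are `(g - lo)/(hi - lo)`.
Uniform spatial sampling uses a cover of axis-aligned cells: pick a cell
uniformly, a point uniformly inside it, reject infeasible points, and keep
feasible ones with probability `vol(cell)/vol_max` — the thinning exactly
cancels the density advantage of small cells, so accepted points are
uniform on the APS for *any* cover that contains it.  Cell classification
is probabilistic (random probes, corners, presample containment, and a 4x
denser probe round before any discard); a depth-1 cover is the bounding
box itself and reduces to plain rejection, which is both the correctness
baseline in tests and the default in seven dimensions where covers stop
paying for themselves.  Rejection uses a 64-point coarse screening grid
with survivors confirmed at the oracle's default 200-point grid.

## Allodynia surface and shortest paths

A circuit is allodynic iff its output population can cross threshold for
some rate in [10, 20] Hz, i.e. iff the output-Abeta coupling is at least

    h(g_rest) = min_f [ (V_thr - V_rest) + inhibitory - excitatory drive ] / f.

Shortest paths to the surface `g_out = h(g_rest)` are computed in
normalized coordinates (raw distances are not comparable across
couplings).  Rather than constrained optimization on an implicit surface,
the equality is eliminated: the surface is parameterized by all other
couplings plus the stimulus rate, with the output coordinate given by the
threshold expression at that rate.  The lifted surface contains the true
surface and lies inside the closed allodynic region, whose nearest point
to any outside point is on the true surface — so the lifted minimum equals
the true one.  Multi-start L-BFGS-B (default 20 starts: the origin's own
coordinates plus uniform draws; bounds enforce raw nonnegativity and allow
normalized values up to 2.5, since the surface exits the unit cube
upward) recovers the global minimum; converged non-global starts,
deduplicated at 1e-3 normalized distance, supply the nearby local minima,
reported when within 1.5x the global length.  Ties break deterministically
(smallest stimulus rate, then lexicographic).  Correctness is checked
against an exhaustive discretization of the lifted surface (1% tolerance).

## Clustering and mechanism labels

Displacement vectors (not unit directions — path length carries
information about sensitivity) are clustered with DBSCAN, minpts 5, at the
smallest Euclidean radius leaving zero noise points, found by bisection
between the smallest positive pairwise distance and the data diameter
(relative tolerance 1e-4).  Labels are renumbered by descending cluster
size.  A cluster is "release-dominated" when its largest mean-displacement
component is a decrease of an Abeta-to-inhibitory coupling,
"escape-dominated" when it is a decrease of an inhibitory-to-excitatory
coupling, otherwise "mixed".

## Pipeline scales and seeds

Default study conditions: 1000 hierarchical presamples define each box;
1000 uniform APS samples for the 3- and 5-dimensional circuits and 1200
for the 7-dimensional one (below ~1000 points the most isolated
displacement vectors inflate the zero-noise DBSCAN radius until the sparse
fourth mechanism family merges away); 20 optimizer starts per point;
minpts 5.
Cluster counts and fractions are stable at these sizes; fractions carry
binomial noise of about +/-1.6 percentage points at n = 1000.  Every
stochastic stage draws its own child seed from the master seed via
`numpy.random.SeedSequence`, so reruns are byte-identical and stages can
be reproduced in isolation.

## Known limitations

* The constraint quantifier for ablation-induced allodynia is an
  interpretation (see above); the static circuit's whole-range version is
  unsatisfiable and was weakened minimally to the 10-Hz form.
* The cover is probabilistically, not provably, a superset of the APS;
  uniformity is therefore validated statistically against plain rejection
  rather than certified.
* Small side clusters (a few percent of points, near the symmetric ridge
  of the static circuit where two mechanisms tie) depend on sample size
  and the zero-noise radius; the two dominant mechanism classes are
  robust.
* Ablated populations are modeled as output-silent only; no homeostatic
  rebalancing of the remaining circuit is attempted.
* All allodynia decisions are steady-state; simulation is illustrative.
  "Sustained firing" in demo traces (mean output rate > 1 Hz over the
  final 0.2 s of the stimulus window) is a display heuristic, never an
  analysis criterion.
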
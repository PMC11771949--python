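"""End-to-end analysis pipeline with provenance.

Stages per circuit: hierarchical presample -> normalization box -> rectangle
cover -> uniform APS sample -> shortest paths to the allodynia surface ->
density-based clustering -> cluster report.  Every stochastic stage gets its
own child seed spawned from the master seed, all artifacts embed the
configuration hash and seeds, and reruns with the same configuration are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .circuits import get_circuit
from .clustering import (
    ClusterReport,
    characterize_clusters,
    cluster_displacements,
    select_epsilon,
)
from .constraints import normalize, presample_hierarchical
from .dynamics import simulate_trace
from .sampling import build_cover, sample_aps_uniform
from .stimulus import generate_abeta_trace
from .surface import shortest_paths

__all__ = ["RunConfig", "PipelineResult", "run_full_analysis",
           "demo_cluster_traces"]

log = logging.getLogger("dorsalhorn")

#: default cover depths per circuit: deeper covers pay off in low dimension;
#: in 7 dimensions the bounding box (depth 1, plain rejection) is cheapest.
DEFAULT_DEPTH = {"simple": 3, "static": 2, "dynamic": 1}


@dataclass
class RunConfig:
    """All knobs of one full-analysis run."""

    circuit: str = "simple"
    n_presample: int = 1000
    n_sample: int = 1000
    depth: int | None = None          # cover depth; None = per-circuit default
    probes_per_cell: int = 8
    n_starts: int = 20
    factor: float = 1.5
    minpts: int = 5
    dt: float = 1e-3
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        if min(self.n_presample, self.n_sample, self.n_starts) < 1:
            raise ValueError("counts must be positive")
        if self.depth is None:
            self.depth = DEFAULT_DEPTH.get(self.circuit, 1)

    def config_hash(self) -> str:
        d = asdict(self)
        d.pop("outdir", None)  # where artifacts land is not part of the run
        payload = json.dumps(d, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def stage_seeds(self) -> dict[str, int]:
        ss = np.random.SeedSequence(self.seed)
        names = ["presample", "cover", "sample", "paths", "demo"]
        return {
            nm: int(child.generate_state(1)[0] % (2 ** 31))
            for nm, child in zip(names, ss.spawn(len(names)))
        }


@dataclass
class PipelineResult:
    config: RunConfig
    box: "object"
    cover: "object"
    sample: "object"
    paths: list
    report: ClusterReport
    timings: dict[str, float] = field(default_factory=dict)


def _write_csv(df: pd.DataFrame, path: Path, meta: dict) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("# " + json.dumps(meta, sort_keys=True) + "\n")
        df.to_csv(fh, index=False, float_format="%.12g", lineterminator="\n")


def run_full_analysis(config: RunConfig) -> PipelineResult:
    """Run every stage for one circuit; optionally write artifacts.

    Artifacts (when ``config.outdir`` is set): presample.csv, box.json,
    sample.csv, paths.csv, clusters.json, run.log -- all embedding the
    config hash and stage seeds.
    """
    spec = get_circuit(config.circuit)
    seeds = config.stage_seeds()
    meta = {"config_hash": config.config_hash(), "circuit": config.circuit,
            "seeds": seeds}
    timings: dict[str, float] = {}

    def stage(name):
        log.info("stage %s (circuit=%s seed=%s)", name, config.circuit,
                 seeds.get(name))
        return time.perf_counter()

    t = stage("presample")
    try:
        pre, box = presample_hierarchical(spec, config.n_presample,
                                          seed=seeds["presample"])
    except Exception as exc:  # pragma: no cover - stage context
        raise RuntimeError(f"presample stage failed: {exc}") from exc
    timings["presample"] = time.perf_counter() - t

    t = stage("cover")
    cover = build_cover(spec, box, depth=config.depth,
                        probes_per_cell=config.probes_per_cell,
                        seed=seeds["cover"], presample=pre)
    timings["cover"] = time.perf_counter() - t

    t = stage("sample")
    sample = sample_aps_uniform(spec, cover, box, config.n_sample,
                                seed=seeds["sample"])
    timings["sample"] = time.perf_counter() - t

    t = stage("paths")
    paths = shortest_paths(spec, sample.normalized, box,
                           n_starts=config.n_starts, seed=seeds["paths"],
                           factor=config.factor)
    timings["paths"] = time.perf_counter() - t

    t = stage("cluster")
    disp = np.array([p.displacement for p in paths])
    eps = select_epsilon(disp, minpts=config.minpts)
    labels = cluster_displacements(disp, eps, minpts=config.minpts)
    report = characterize_clusters(spec, sample.normalized, paths, labels,
                                   eps, minpts=config.minpts)
    timings["cluster"] = time.perf_counter() - t

    if config.outdir is not None:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        from .surface import paths_to_frame

        _write_csv(pd.DataFrame(pre, columns=list(spec.hierarchy)),
                   out / "presample.csv", meta)
        with open(out / "box.json", "w") as fh:
            json.dump({**meta, "box": box.to_dict()}, fh, indent=2,
                      sort_keys=True)
        _write_csv(sample.to_frame(spec.hierarchy), out / "sample.csv", meta)
        pf = paths_to_frame(spec, paths)
        pf["cluster"] = report.labels
        _write_csv(pf, out / "paths.csv", meta)
        with open(out / "clusters.json", "w") as fh:
            json.dump({**meta, "report": report.to_dict()}, fh, indent=2,
                      sort_keys=True)
        with open(out / "run.log", "w") as fh:
            for k, v in timings.items():
                fh.write(f"{k}\tseed={seeds.get(k, '')}\t{v:.3f}s\n")
    return PipelineResult(config=config, box=box, cover=cover, sample=sample,
                          paths=paths, report=report, timings=timings)


def smallest_allodynic_rate(spec, g_raw, resolution: float = 0.5) -> float | None:
    """Smallest mean Abeta rate in range that makes ``g_raw`` allodynic.

    Scanned at ``resolution`` Hz on the steady-state threshold condition of
    the output population.
    """
    from .circuits import steady_state

    g = spec.coupling_dict(np.asarray(g_raw, dtype=float))
    pop = spec.params(spec.output)
    f_grid = np.arange(spec.f_range[0], spec.f_range[1] + 1e-9, resolution)
    V = steady_state(spec, g, f_grid).voltage[spec.output]
    crossing = np.asarray(V) >= pop.V_thr - 1e-9
    if not crossing.any():
        return None
    return float(f_grid[np.argmax(crossing)])


def demo_cluster_traces(
    config: RunConfig,
    result: PipelineResult,
    cluster: int,
    T: float = 1.0,
    window: tuple[float, float] = (0.2, 0.7),
):
    """Paired simulations: cluster-mean subcircuit vs its surface image.

    Both parameterizations are driven by the same 300-fiber Poisson Abeta
    bundle whose mean stimulus rate is the smallest allodynia-inducing rate
    (0.5 Hz scan) for the on-surface subcircuit.  Returns
    (mean_trace, surface_trace, stimulus).
    """
    report = result.report
    if cluster not in report.fractions:
        raise KeyError(f"no cluster {cluster} in report")
    spec = get_circuit(config.circuit)
    box = result.box
    mean_hat = report.mean_couplings[cluster]
    mean_raw = normalize(mean_hat, box, inverse=True)
    if smallest_allodynic_rate(spec, mean_raw) is not None:
        raise ValueError("cluster mean is already allodynic; report is "
                         "inconsistent with the APS definition")
    # surface image of the cluster mean: its own nearest surface point
    from .surface import shortest_path

    path = shortest_path(spec, mean_hat, box, n_starts=config.n_starts,
                         seed=config.stage_seeds()["demo"], factor=config.factor)
    surf_raw = path.surface_point.raw
    f_ab = smallest_allodynic_rate(spec, surf_raw)
    if f_ab is None:  # boundary point: its own minimizing rate crosses
        f_ab = path.surface_point.f_nearest
    stim = generate_abeta_trace(f_ab, t_on=window[0], t_off=window[1], T=T,
                                dt=config.dt,
                                seed=config.stage_seeds()["demo"])
    tr_mean = simulate_trace(spec, spec.coupling_dict(mean_raw), stim,
                             dt=config.dt)
    tr_surf = simulate_trace(spec, spec.coupling_dict(surf_raw), stim,
                             dt=config.dt)
    return tr_mean, tr_surf, stim
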
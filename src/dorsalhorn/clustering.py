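"""Density-based clustering of shortest-path displacement vectors.

Each APS point contributes a displacement vector (its shortest normalized
path to the allodynia surface).  Vectors are clustered with DBSCAN under the
Euclidean metric using the smallest neighborhood radius that leaves no
outliers (minpts = 5); with that choice every point belongs to a cluster and
the partition is a property of the data rather than of a tuned radius.
Clusters are then read as allodynia mechanisms: a dominant decrease in an
Abeta-to-inhibitory coupling releases the excitatory population from
inhibition, a dominant decrease in an inhibitory-to-excitatory coupling
lets it escape inhibition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.cluster import DBSCAN

from .circuits import ABETA, SubcircuitSpec

__all__ = [
    "ClusterReport",
    "select_epsilon",
    "cluster_displacements",
    "characterize_clusters",
]


def _n_noise(vectors: np.ndarray, eps: float, minpts: int) -> int:
    labels = DBSCAN(eps=eps, min_samples=minpts).fit_predict(vectors)
    return int((labels == -1).sum())


def select_epsilon(
    vectors: np.ndarray, minpts: int = 5, rtol: float = 1e-4
) -> float:
    """Smallest DBSCAN radius with zero noise points (bisection).

    Bracketed between the smallest positive pairwise distance and the data
    diameter; the diameter always yields a single all-inclusive cluster, so
    a zero-noise radius exists.
    """
    vectors = np.asarray(vectors, dtype=float)
    if len(vectors) == 0:
        raise ValueError("empty input")
    if len(vectors) < minpts:
        raise ValueError("need at least minpts vectors")
    d = pdist(vectors)
    hi = float(d.max())
    if hi == 0.0:  # all identical
        return 1e-12
    lo = float(d[d > 0].min())
    if _n_noise(vectors, lo, minpts) == 0:
        return lo
    while (hi - lo) / hi > rtol:
        mid = 0.5 * (lo + hi)
        if _n_noise(vectors, mid, minpts) == 0:
            hi = mid
        else:
            lo = mid
    return hi


def cluster_displacements(
    vectors: np.ndarray, eps: float, minpts: int = 5
) -> np.ndarray:
    """DBSCAN labels renumbered by descending cluster size (0 = largest).

    With the radius from :func:`select_epsilon` no point is noise; ties in
    size break on the smallest original member index, so the labeling is
    deterministic and independent of input order up to relabeling.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    raw = DBSCAN(eps=eps, min_samples=minpts).fit_predict(
        np.asarray(vectors, dtype=float))
    out = np.full_like(raw, -1)
    ids = [l for l in np.unique(raw) if l != -1]
    sizes = {l: (raw == l).sum() for l in ids}
    first = {l: int(np.argmax(raw == l)) for l in ids}
    for new, l in enumerate(sorted(ids, key=lambda l: (-sizes[l], first[l]))):
        out[raw == l] = new
    return out


@dataclass
class ClusterReport:
    """Cluster composition, geometry and mechanism annotations."""

    spec_name: str
    eps: float
    minpts: int
    labels: np.ndarray
    fractions: dict[int, float]                  # % of the APS
    mean_couplings: dict[int, np.ndarray]        # normalized
    std_couplings: dict[int, np.ndarray]
    mean_displacement: dict[int, np.ndarray]
    distances: dict[int, np.ndarray]
    mechanism: dict[int, str]
    correlation: np.ndarray                      # whole-sample Pearson
    names: tuple[str, ...] = ()

    @property
    def n_clusters(self) -> int:
        return len(self.fractions)

    def to_dict(self) -> dict:
        return {
            "circuit": self.spec_name,
            "eps": self.eps,
            "minpts": self.minpts,
            "n_clusters": self.n_clusters,
            "names": list(self.names),
            "clusters": {
                str(k): {
                    "fraction_pct": self.fractions[k],
                    "mean_couplings_hat": self.mean_couplings[k].tolist(),
                    "std_couplings_hat": self.std_couplings[k].tolist(),
                    "mean_displacement": self.mean_displacement[k].tolist(),
                    "mechanism": self.mechanism[k],
                    "mean_distance": float(self.distances[k].mean()),
                }
                for k in self.fractions
            },
            "correlation": self.correlation.tolist(),
        }


def _connection_kind(spec: SubcircuitSpec, name: str) -> str:
    for c in spec.connections:
        if c.name == name:
            if c.source == ABETA:
                return ("abeta_to_inhibitory"
                        if spec.params(c.target).role == "inhibitory"
                        else "abeta_to_excitatory")
            if spec.params(c.source).role == "inhibitory":
                return "inhibitory_to_excitatory"
            return "excitatory_to_excitatory"
    raise KeyError(name)


def _mechanism(spec: SubcircuitSpec, mean_disp: np.ndarray) -> str:
    i = int(np.argmax(np.abs(mean_disp)))
    kind = _connection_kind(spec, spec.hierarchy[i])
    if mean_disp[i] < 0 and kind == "abeta_to_inhibitory":
        return "release-dominated"
    if mean_disp[i] < 0 and kind == "inhibitory_to_excitatory":
        return "escape-dominated"
    return "mixed"


def characterize_clusters(
    spec: SubcircuitSpec,
    sample_hat: np.ndarray,
    paths,
    labels: np.ndarray,
    eps: float,
    minpts: int = 5,
) -> ClusterReport:
    """Summarize clusters of APS points by coupling statistics and paths."""
    sample_hat = np.asarray(sample_hat, dtype=float)
    if not (len(sample_hat) == len(paths) == len(labels)):
        raise ValueError("sample, paths and labels must be aligned")
    disp = np.array([p.displacement for p in paths])
    lengths = np.array([p.length for p in paths])
    n = len(labels)
    fractions, meang, stdg, meand, dists, mech = {}, {}, {}, {}, {}, {}
    for k in sorted(set(int(l) for l in labels)):
        m = labels == k
        fractions[k] = 100.0 * m.sum() / n
        meang[k] = sample_hat[m].mean(axis=0)
        stdg[k] = sample_hat[m].std(axis=0)
        meand[k] = disp[m].mean(axis=0)
        dists[k] = lengths[m]
        mech[k] = _mechanism(spec, meand[k])
    corr = np.corrcoef(sample_hat, rowvar=False)
    return ClusterReport(
        spec_name=spec.name,
        eps=eps,
        minpts=minpts,
        labels=np.asarray(labels),
        fractions=fractions,
        mean_couplings=meang,
        std_couplings=stdg,
        mean_displacement=meand,
        distances=dists,
        mechanism=mech,
        correlation=corr,
        names=spec.hierarchy,
    )
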
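"""Network-based statistic: component-level inference on edge differences.

Edgewise two-sample t statistics are thresholded at a primary height
(default t = 2.62); connected components of the surviving edges are the
candidate effects, and family-wise-error-corrected p-values come from the
permutation distribution of the *maximum* component size (edge count) under
group-label relabeling.  The two directions (patient < control and
patient > control) are analyzed separately by default.

Edge values are the raw FA weights of the unthresholded matrices; only edges
present (nonzero) in at least a minimum fraction of subjects (default 50%)
enter the analysis, since t statistics on near-absent tracts are unstable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_array
from scipy.sparse.csgraph import connected_components

from .dataio import Cohort
from .exceptions import ConfigError
from .group_stats import _pooled_t


@dataclass(frozen=True)
class NBSConfig:
    t_threshold: float = 2.62
    n_perm: int = 10_000
    alpha: float = 0.05
    seed: int = 0
    direction: str = "both"        # "less" | "greater" | "both"
    min_presence: float = 0.5      # edge kept if nonzero in >= this fraction

    def __post_init__(self):
        if self.t_threshold <= 0:
            raise ConfigError("t_threshold must be > 0")
        if self.n_perm < 100:
            raise ConfigError("n_perm must be >= 100")
        if self.direction not in ("less", "greater", "both"):
            raise ConfigError(f"unknown direction {self.direction!r}")


@dataclass(frozen=True)
class NBSComponent:
    nodes: tuple[int, ...]
    edges: tuple[tuple[int, int], ...]
    size: int                      # number of edges
    p_fwer: float
    direction: str                 # "patient<control" | "patient>control"

    def to_dict(self) -> dict:
        return {
            "nodes": list(self.nodes), "edges": [list(e) for e in self.edges],
            "size": self.size, "p_fwer": self.p_fwer, "direction": self.direction,
        }


@dataclass(frozen=True)
class NBSResult:
    components: tuple[NBSComponent, ...]
    null_max_sizes: dict
    config: NBSConfig
    n_zero_variance_edges: int

    def significant(self, alpha: float | None = None) -> list[NBSComponent]:
        a = self.config.alpha if alpha is None else alpha
        return [c for c in self.components if c.p_fwer < a]

    def to_dict(self) -> dict:
        return {
            "components": [c.to_dict() for c in self.components],
            "null_max_sizes": self.null_max_sizes,
            "t_threshold": self.config.t_threshold,
            "n_perm": self.config.n_perm,
            "alpha": self.config.alpha,
            "n_zero_variance_edges": self.n_zero_variance_edges,
        }

    def with_region_names(self, atlas) -> dict:
        out = self.to_dict()
        for comp, cdict in zip(self.components, out["components"]):
            cdict["node_names"] = [atlas.names[i] for i in comp.nodes]
            cdict["edge_names"] = [
                [atlas.names[i], atlas.names[j]] for i, j in comp.edges
            ]
        return out


def edgewise_t(edge_values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Two-sample t per edge (group True minus group False).

    ``edge_values`` is (n_subjects, n_edges); returns one t per edge.
    Zero-variance edges (including edges absent in every subject) get t = 0.
    """
    labels = np.asarray(labels, dtype=bool)
    n_a = int(labels.sum())
    n_b = int((~labels).sum())
    if n_a < 2 or n_b < 2:
        raise ConfigError("need >= 2 subjects per group for edgewise t")
    a = edge_values[labels]
    b = edge_values[~labels]
    return _pooled_t(a.sum(0), (a**2).sum(0), n_a, b.sum(0), (b**2).sum(0), n_b)


def edgewise_t_matrix(cohort: Cohort) -> np.ndarray:
    """Symmetric N x N matrix of patient-minus-control edgewise t statistics."""
    n = cohort.atlas.n
    iu, ju = np.triu_indices(n, 1)
    stacked = cohort.stack_matrices()
    x = stacked[:, iu, ju]
    t = edgewise_t(x, cohort.groups == "patient")
    out = np.zeros((n, n))
    out[iu, ju] = t
    out[ju, iu] = t
    return out


def supra_components(
    t_matrix: np.ndarray, t_threshold: float, sign: int = 1
) -> list[tuple[tuple[int, ...], tuple[tuple[int, int], ...]]]:
    """Connected components of the graph of supra-threshold edges.

    ``sign=+1`` keeps edges with t >= threshold, ``sign=-1`` those with
    t <= -threshold.  Returns (nodes, edges) per component, components with
    at least one edge only.
    """
    t = np.asarray(t_matrix)
    mask = (sign * np.triu(t, 1)) >= t_threshold
    iu, ju = np.nonzero(mask)
    if len(iu) == 0:
        return []
    n = t.shape[0]
    adj = coo_array((np.ones(len(iu)), (iu, ju)), shape=(n, n))
    _, labels = connected_components(adj, directed=False)
    comps = {}
    for i, j in zip(iu, ju):
        comps.setdefault(labels[i], []).append((int(i), int(j)))
    out = []
    for edges in comps.values():
        nodes = tuple(sorted({v for e in edges for v in e}))
        out.append((nodes, tuple(sorted(edges))))
    out.sort(key=lambda ne: (-len(ne[1]), ne[0]))
    return out


def _max_component_size(t_vec: np.ndarray, iu, ju, n, t_threshold, sign) -> int:
    """Largest supra-threshold component size (edges) — permutation inner loop."""
    keep = (sign * t_vec) >= t_threshold
    k = int(keep.sum())
    if k <= 1:
        return k
    ii, jj = iu[keep], ju[keep]
    adj = coo_array((np.ones(k), (ii, jj)), shape=(n, n))
    _, labels = connected_components(adj, directed=False)
    counts = np.bincount(labels[ii], minlength=0)
    return int(counts.max())


def nbs_test(cohort: Cohort, config: NBSConfig = NBSConfig()) -> NBSResult:
    """Full NBS: observed components and FWER p-values by label permutation.

    p_fwer(component) = (1 + #{max null component size >= observed size})
    / (n_perm + 1), with the null built from the permutation distribution of
    the maximum component size for the same direction.
    """
    n = cohort.atlas.n
    iu, ju = np.triu_indices(n, 1)
    stacked = cohort.stack_matrices()
    x_all = stacked[:, iu, ju]
    labels = cohort.groups == "patient"

    presence = (x_all > 0).mean(axis=0)
    universe = presence >= config.min_presence
    x = x_all[:, universe]
    iu_u, ju_u = iu[universe], ju[universe]

    t_obs = edgewise_t(x, labels)
    n_zero_var = int(np.count_nonzero(t_obs == 0))

    directions = {"less": (-1,), "greater": (1,), "both": (-1, 1)}[config.direction]
    rng = np.random.default_rng(config.seed)
    n_subj = len(labels)
    n_a = int(labels.sum())

    # permutation null of the maximum component size, shared across components
    null_max = {s: np.zeros(config.n_perm, dtype=int) for s in directions}
    ssq_total = (x**2).sum(axis=0)
    sum_total = x.sum(axis=0)
    for p in range(config.n_perm):
        idx = rng.permutation(n_subj)[:n_a]
        xa = x[idx]
        sum_a = xa.sum(axis=0)
        ssq_a = (xa**2).sum(axis=0)
        t_perm = _pooled_t(sum_a, ssq_a, n_a, sum_total - sum_a,
                           ssq_total - ssq_a, n_subj - n_a)
        for s in directions:
            null_max[s][p] = _max_component_size(
                t_perm, iu_u, ju_u, n, config.t_threshold, s
            )

    components = []
    tmat = np.zeros((n, n))
    tmat[iu_u, ju_u] = t_obs
    tmat[ju_u, iu_u] = t_obs
    for s in directions:
        name = "patient<control" if s == -1 else "patient>control"
        for nodes, edges in supra_components(tmat, config.t_threshold, sign=s):
            size = len(edges)
            p_fwer = (1 + int(np.count_nonzero(null_max[s] >= size))) / (config.n_perm + 1)
            components.append(
                NBSComponent(nodes=nodes, edges=edges, size=size,
                             p_fwer=float(p_fwer), direction=name)
            )
    components.sort(key=lambda c: c.p_fwer)
    null_summary = {
        ("patient<control" if s == -1 else "patient>control"): {
            "mean": float(null_max[s].mean()),
            "q95": float(np.quantile(null_max[s], 0.95)),
            "max": int(null_max[s].max()),
        }
        for s in directions
    }
    return NBSResult(
        components=tuple(components), null_max_sizes=null_summary,
        config=config, n_zero_variance_edges=n_zero_var,
    )
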
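"""Global and nodal topological measures of thresholded networks.

Conventions (standard in FA-weighted connectomics):

* weighted shortest-path distance of an edge = 1 / weight, so stronger
  connections are "closer";
* weighted clustering uses the Onnela geometric-mean variant with weights
  normalized by the network maximum;
* characteristic path length on fragmented networks is the mean over finite
  ordered pairs (the number of infinite pairs is reported);
* normalization (gamma, lambda, sigma) divides by the mean metric over
  degree-preserving randomized references (double-edge swaps; in the weighted
  case the topology is rewired and the original weight multiset is
  reassigned to the rewired edges in random order).

Metric kernels are vectorized with numpy/scipy on the dense N x N adjacency;
betweenness delegates to the Brandes algorithm in networkx.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from numba import njit
from scipy.sparse import csr_array
from scipy.sparse.csgraph import shortest_path

from .dataio import Cohort
from .exceptions import ConfigError
from .thresholding import SparsityGrid, ThresholdedNetwork, apply_sparsity, metric_auc

GLOBAL_METRICS = ("cp", "lp", "gamma", "lam", "sigma", "eloc", "eglob")
NODAL_MEASURES = ("degree", "betweenness", "efficiency")


@dataclass(frozen=True)
class GlobalMetrics:
    """The seven global topological measures of one network."""

    cp: float
    lp: float
    gamma: float
    lam: float
    sigma: float
    eloc: float
    eglob: float

    def to_dict(self) -> dict:
        return {
            "cp": self.cp, "lp": self.lp, "gamma": self.gamma,
            "lam": self.lam, "sigma": self.sigma,
            "eloc": self.eloc, "eglob": self.eglob,
        }


@dataclass(frozen=True)
class NodalMetrics:
    """Per-node centralities: degree (strength when weighted), shortest-path
    betweenness, and nodal efficiency."""

    degree: np.ndarray
    betweenness: np.ndarray
    efficiency: np.ndarray


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def clustering_coefficient(net: ThresholdedNetwork) -> tuple[np.ndarray, float]:
    """Per-node clustering and its mean Cp.

    Binary: triangle density 2 t_i / (k_i (k_i - 1)), zero for degree < 2.
    Weighted: Onnela variant — geometric mean of the triangle's weights
    normalized by the network maximum, averaged over potential triangles.
    """
    a = net.binary
    k = a.sum(axis=1)
    denom = k * (k - 1)
    if net.weighted:
        wmax = net.adjacency.max()
        if wmax == 0:
            return np.zeros(net.n), 0.0
        w3 = np.cbrt(net.adjacency / wmax)
        tri = np.diagonal(w3 @ w3 @ w3)
    else:
        tri = np.diagonal(a @ a @ a)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, tri / np.where(denom > 0, denom, 1), 0.0)
    return c, float(c.mean())


# ---------------------------------------------------------------------------
# shortest-path measures
# ---------------------------------------------------------------------------

def distance_matrix(net: ThresholdedNetwork) -> np.ndarray:
    """All-pairs shortest-path distances; edge length = 1/weight (1 if binary)."""
    if net.weighted:
        with np.errstate(divide="ignore"):
            lengths = np.where(net.adjacency > 0, 1.0 / net.adjacency, 0.0)
    else:
        lengths = net.binary
    sp = csr_array(lengths)
    return shortest_path(sp, method="D", directed=False)


def path_metrics(
    net: ThresholdedNetwork, largest_component_only: bool = False
) -> tuple[float, float, np.ndarray, int]:
    """Characteristic path length, global efficiency, nodal efficiency.

    Returns ``(lp, eglob, nodal_efficiency, n_infinite_pairs)``.  Lp averages
    finite ordered pairs only; efficiencies use 1/d with 1/inf = 0, so a
    disconnected node simply contributes zeros.  With
    ``largest_component_only`` the Lp is restricted to pairs inside the
    largest connected component (efficiencies are unaffected; they already
    treat unreachable pairs as zero).
    """
    d = distance_matrix(net)
    if largest_component_only:
        from scipy.sparse.csgraph import connected_components

        _, labels = connected_components(csr_array(net.binary), directed=False)
        major = labels == np.bincount(labels).argmax()
        lp_major = _path_metrics_from_distances(d[np.ix_(major, major)])[0]
        _, eglob, nodal_eff, n_inf = _path_metrics_from_distances(d)
        return lp_major, eglob, nodal_eff, n_inf
    return _path_metrics_from_distances(d)


def _path_metrics_from_distances(d: np.ndarray) -> tuple[float, float, np.ndarray, int]:
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    n_inf = int(off.sum() - finite.sum())
    lp = float(d[finite].mean()) if finite.any() else np.inf
    inv = np.zeros_like(d)
    inv[finite] = 1.0 / d[finite]
    nodal_eff = inv.sum(axis=1) / (n - 1)
    eglob = float(inv[off].mean())
    return lp, eglob, nodal_eff, n_inf


def global_efficiency(net: ThresholdedNetwork) -> float:
    return path_metrics(net)[1]


def characteristic_path_length(net: ThresholdedNetwork) -> float:
    return path_metrics(net)[0]


def local_efficiency(net: ThresholdedNetwork) -> tuple[np.ndarray, float]:
    """Per-node local efficiency and its mean Eloc.

    The local efficiency of node i is the global efficiency of the subgraph
    induced by i's neighbors; nodes with degree < 2 score 0.
    """
    a = net.binary
    vals = np.zeros(net.n)
    for i in range(net.n):
        nbrs = np.flatnonzero(a[i])
        if len(nbrs) < 2:
            continue
        sub = ThresholdedNetwork(
            adjacency=net.adjacency[np.ix_(nbrs, nbrs)],
            sparsity=net.sparsity,
            weighted=net.weighted,
        )
        vals[i] = path_metrics(sub)[1]
    return vals, float(vals.mean())


# ---------------------------------------------------------------------------
# betweenness and nodal bundle
# ---------------------------------------------------------------------------

def betweenness(net: ThresholdedNetwork) -> np.ndarray:
    """Unnormalized shortest-path betweenness (Brandes), fractional credit on
    equal-length paths; each unordered pair counted once."""
    if net.weighted:
        with np.errstate(divide="ignore"):
            lengths = np.where(net.adjacency > 0, 1.0 / net.adjacency, 0.0)
        g = nx.from_numpy_array(lengths)
        bc = nx.betweenness_centrality(g, normalized=False, weight="weight")
    else:
        g = nx.from_numpy_array(net.binary)
        bc = nx.betweenness_centrality(g, normalized=False)
    return np.array([bc[i] for i in range(net.n)])


def degree(net: ThresholdedNetwork) -> np.ndarray:
    """Binary degree, or strength (sum of weights) for weighted networks."""
    return net.adjacency.sum(axis=1) if net.weighted else net.binary.sum(axis=1)


def nodal_metrics(net: ThresholdedNetwork) -> NodalMetrics:
    _, _, eff, _ = path_metrics(net)
    return NodalMetrics(degree=degree(net), betweenness=betweenness(net), efficiency=eff)


# ---------------------------------------------------------------------------
# degree-preserving random references
# ---------------------------------------------------------------------------

@njit(cache=False)
def _swap_core(ei, ej, adj, n_attempts, seed):  # pragma: no cover - jitted
    np.random.seed(seed)
    m = ei.shape[0]
    n_success = 0
    for _ in range(n_attempts):
        a = np.random.randint(0, m)
        b = np.random.randint(0, m)
        if a == b:
            continue
        u, v = ei[a], ej[a]
        x, y = ei[b], ej[b]
        if np.random.randint(0, 2) == 1:
            x, y = y, x
        if u == x or u == y or v == x or v == y:
            continue
        if adj[u, x] or adj[v, y]:
            continue
        adj[u, v] = False
        adj[v, u] = False
        adj[x, y] = False
        adj[y, x] = False
        adj[u, x] = True
        adj[x, u] = True
        adj[v, y] = True
        adj[y, v] = True
        ei[a], ej[a] = (u, x) if u < x else (x, u)
        ei[b], ej[b] = (v, y) if v < y else (y, v)
        n_success += 1
    return n_success


def random_reference(
    net: ThresholdedNetwork,
    n_rand: int = 100,
    n_swaps_per_edge: int = 10,
    seed: int = 0,
) -> list[ThresholdedNetwork]:
    """Degree-preserving randomized references by double-edge swaps.

    Each reference applies ``n_swaps_per_edge * n_edges`` attempted
    Maslov–Sneppen swaps; the binary degree sequence is preserved exactly.
    For weighted networks the topology is rewired and the original weight
    multiset is reassigned to the rewired edges in random order.
    """
    iu, ju = np.nonzero(np.triu(net.adjacency, 1))
    m = len(iu)
    if m < 2:
        raise ConfigError("random_reference needs a network with >= 2 edges")
    weights = net.adjacency[iu, ju].copy()
    refs = []
    rng = np.random.default_rng(seed)
    for r in range(n_rand):
        ei = iu.astype(np.int64).copy()
        ej = ju.astype(np.int64).copy()
        adj = net.adjacency > 0
        sub_seed = int(rng.integers(0, 2**31 - 1))
        _swap_core(ei, ej, adj.copy(), int(n_swaps_per_edge) * m, sub_seed)
        new = np.zeros_like(net.adjacency)
        if net.weighted:
            vals = rng.permutation(weights)
        else:
            vals = np.ones(m)
        new[ei, ej] = vals
        new[ej, ei] = vals
        refs.append(
            ThresholdedNetwork(adjacency=new, sparsity=net.sparsity, weighted=net.weighted)
        )
    return refs


def normalized_globals(
    net: ThresholdedNetwork, refs: list[ThresholdedNetwork]
) -> GlobalMetrics:
    """All seven global metrics, normalizing Cp and Lp by the reference means.

    gamma = Cp / <Cp_rand>, lambda = Lp / <Lp_rand>, sigma = gamma / lambda.
    """
    if not refs:
        raise ConfigError("normalized_globals needs at least one reference network")
    _, cp = clustering_coefficient(net)
    lp, eglob, _, _ = path_metrics(net)
    _, eloc = local_efficiency(net)
    cp_refs = np.array([clustering_coefficient(r)[1] for r in refs])
    lp_refs = np.array([path_metrics(r)[0] for r in refs])
    cp_bar = cp_refs.mean()
    lp_bar = lp_refs.mean()
    if cp_bar == 0 or not np.isfinite(cp_bar) or lp_bar == 0 or not np.isfinite(lp_bar):
        raise ConfigError(
            f"undefined normalization: mean reference Cp={cp_bar}, Lp={lp_bar}"
        )
    gamma = cp / cp_bar
    lam = lp / lp_bar
    return GlobalMetrics(
        cp=cp, lp=lp, gamma=float(gamma), lam=float(lam),
        sigma=float(gamma / lam), eloc=eloc, eglob=eglob,
    )


def small_worldness(
    net: ThresholdedNetwork,
    n_rand: int = 100,
    n_swaps_per_edge: int = 10,
    seed: int = 0,
) -> float:
    refs = random_reference(net, n_rand, n_swaps_per_edge, seed)
    return normalized_globals(net, refs).sigma


# ---------------------------------------------------------------------------
# cohort-level metric curves and AUC tables
# ---------------------------------------------------------------------------

def _fast_globals(net, refs):
    """cp/lp/gamma/lam/sigma without the Eloc loop (used in metric curves when
    eloc/eglob are not requested)."""
    _, cp = clustering_coefficient(net)
    lp, eglob, _, _ = path_metrics(net)
    cp_bar = np.mean([clustering_coefficient(r)[1] for r in refs])
    lp_bar = np.mean([path_metrics(r)[0] for r in refs])
    gamma = cp / cp_bar
    lam = lp / lp_bar
    return {"cp": cp, "lp": lp, "gamma": gamma, "lam": lam,
            "sigma": gamma / lam, "eglob": eglob}


def global_auc_table(
    cohort: Cohort,
    grid: SparsityGrid,
    weighted: bool = True,
    n_rand: int = 100,
    n_swaps_per_edge: int = 10,
    seed: int = 0,
    metrics: tuple[str, ...] = GLOBAL_METRICS,
) -> pd.DataFrame:
    """Per-subject AUC of each global metric over the sparsity grid.

    Returns a DataFrame with columns subject_id, group, and one AUC column
    per requested metric.  ``metrics`` can be restricted (e.g. to
    ``("cp", "gamma", "sigma")``) to skip the more expensive measures.
    """
    unknown = set(metrics) - set(GLOBAL_METRICS)
    if unknown:
        raise ConfigError(f"unknown global metrics {sorted(unknown)}")
    s_values = grid.values
    need_eloc = "eloc" in metrics
    rng = np.random.default_rng(seed)
    rows = []
    for mat, rec in cohort:
        sub_seed = int(rng.integers(0, 2**31 - 1))
        curves = {m: [] for m in metrics}
        for s_i, s in enumerate(s_values):
            net = apply_sparsity(mat, float(s), weighted=weighted)
            refs = random_reference(
                net, n_rand, n_swaps_per_edge, seed=(sub_seed + s_i) % (2**31 - 1)
            )
            vals = _fast_globals(net, refs)
            if need_eloc:
                vals["eloc"] = local_efficiency(net)[1]
            for m in metrics:
                curves[m].append(vals[m])
        row = {"subject_id": mat.subject_id, "group": rec.group}
        for m in metrics:
            row[m] = metric_auc(s_values, np.array(curves[m]))
        rows.append(row)
    return pd.DataFrame(rows)


def nodal_auc_table(
    cohort: Cohort,
    grid: SparsityGrid,
    weighted: bool = True,
) -> dict[str, pd.DataFrame]:
    """Per-subject AUC of each nodal centrality at every node.

    Returns ``{"degree": df, "betweenness": df, "efficiency": df}``; each df
    has subject rows (with subject_id/group) and one column per atlas region.
    """
    s_values = grid.values
    out = {m: [] for m in NODAL_MEASURES}
    for mat, rec in cohort:
        curves = {m: [] for m in NODAL_MEASURES}
        for s in s_values:
            net = apply_sparsity(mat, float(s), weighted=weighted)
            _, _, eff, _ = path_metrics(net)
            curves["degree"].append(degree(net))
            curves["betweenness"].append(betweenness(net))
            curves["efficiency"].append(eff)
        for m in NODAL_MEASURES:
            auc = metric_auc(s_values, np.array(curves[m]).T)
            out[m].append(
                {"subject_id": mat.subject_id, "group": rec.group,
                 **{name: auc[i] for i, name in enumerate(cohort.atlas.names)}}
            )
    return {m: pd.DataFrame(rows) for m, rows in out.items()}
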
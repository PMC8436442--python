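"""Sparsity thresholding of weighted networks and AUC summarization.

Every subject's network is reduced to the same edge count by keeping the
top-K edges by weight, K = round(S * N(N-1)/2) for a sparsity S.  Metrics are
then computed over a grid of S values and summarized by the trapezoidal area
under the metric-vs-S curve, removing the dependence on any single threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import Cohort, ConnectivityMatrix
from .exceptions import ConfigError, EmptyRangeError


@dataclass(frozen=True)
class SparsityGrid:
    """Arithmetic grid of sparsity values ``s_min, s_min+step, ..., s_max``."""

    s_min: float = 0.10
    s_max: float = 0.34
    step: float = 0.01

    def __post_init__(self):
        if not (0 < self.s_min < self.s_max < 1):
            raise ConfigError(f"need 0 < s_min < s_max < 1, got {self.s_min}, {self.s_max}")
        k = (self.s_max - self.s_min) / self.step
        if abs(k - round(k)) > 1e-9:
            raise ConfigError(
                f"(s_max - s_min)/step = {k} is not an integer; grid must be arithmetic"
            )

    @property
    def values(self) -> np.ndarray:
        n = int(round((self.s_max - self.s_min) / self.step)) + 1
        return np.round(self.s_min + self.step * np.arange(n), 12)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class ThresholdedNetwork:
    """A network at one sparsity level.

    ``adjacency`` is N x N, symmetric, zero-diagonal; binary 0/1 when
    ``weighted`` is False, original weights on kept edges otherwise.
    """

    adjacency: np.ndarray
    sparsity: float
    weighted: bool

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.adjacency, 1)))

    @property
    def binary(self) -> np.ndarray:
        return (self.adjacency > 0).astype(float)


def edge_count(n_nodes: int, sparsity: float) -> int:
    """Number of kept edges: round(S * N(N-1)/2), round half up."""
    m = n_nodes * (n_nodes - 1) // 2
    return int(np.floor(sparsity * m + 0.5))


def _edge_order(weights: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Upper-triangle edges sorted by (weight desc, i asc, j asc).

    The total order makes top-K selection deterministic under ties and makes
    edge sets nested across sparsity levels.
    """
    n = weights.shape[0]
    iu, ju = np.triu_indices(n, 1)
    w = weights[iu, ju]
    # lexsort: last key is primary
    order = np.lexsort((ju, iu, -w))
    return iu[order], ju[order], w[order]


def apply_sparsity(
    matrix: ConnectivityMatrix | np.ndarray,
    sparsity: float,
    weighted: bool = True,
) -> ThresholdedNetwork:
    """Keep exactly ``round(S * N(N-1)/2)`` strongest edges.

    All kept weights are >= all dropped weights; ties at the cut are broken by
    lexicographic (i, j) node order, so the result is deterministic and edge
    sets are nested across S.
    """
    w = matrix.weights if isinstance(matrix, ConnectivityMatrix) else np.asarray(matrix)
    n = w.shape[0]
    if not 0 < sparsity < 1:
        raise ConfigError(f"sparsity must be in (0, 1), got {sparsity}")
    k = edge_count(n, sparsity)
    m = n * (n - 1) // 2
    if k == 0 or k == m:
        warnings.warn(
            f"degenerate threshold: S={sparsity} keeps {k} of {m} edges",
            stacklevel=2,
        )
    ei, ej, ew = _edge_order(w)
    adj = np.zeros_like(w)
    ki, kj, kw = ei[:k], ej[:k], ew[:k]
    vals = kw if weighted else 1.0
    adj[ki, kj] = vals
    adj[kj, ki] = vals
    return ThresholdedNetwork(adjacency=adj, sparsity=sparsity, weighted=weighted)


def metric_auc(
    s_values: np.ndarray, values: np.ndarray, method: str = "trapezoid"
) -> np.ndarray:
    """Area under a metric curve over the sparsity grid.

    ``values`` may be 1-D (one subject) or 2-D (subjects x grid); the AUC is
    linear in the values.  NaNs propagate with a warning.  ``method`` is
    ``"trapezoid"`` (default) or ``"rectangle"`` (left-sum step-width
    rectangles, for parity with toolboxes that integrate that way).
    """
    s = np.asarray(s_values, dtype=float)
    v = np.atleast_2d(np.asarray(values, dtype=float))
    if s.ndim != 1 or len(s) < 2:
        raise ConfigError("metric_auc needs >= 2 grid points")
    if v.shape[-1] != len(s):
        raise ConfigError(f"values last axis {v.shape[-1]} != grid length {len(s)}")
    bad = np.where(~np.isfinite(v))
    if bad[0].size:
        warnings.warn(
            f"NaN/inf in metric curve for subject row(s) {sorted(set(bad[0].tolist()))} "
            f"at S={s[sorted(set(bad[1].tolist()))]}; AUC will propagate NaN",
            stacklevel=2,
        )
    if method == "trapezoid":
        auc = np.trapezoid(v, s, axis=-1)
    elif method == "rectangle":
        auc = (v[..., :-1] * np.diff(s)).sum(axis=-1)
    else:
        raise ConfigError(f"unknown AUC method {method!r}")
    return auc if np.asarray(values).ndim > 1 else float(auc[0])


def select_sparsity_range(
    cohort: Cohort,
    candidate: SparsityGrid | None = None,
    sigma_min: float = 1.1,
    n_rand: int = 20,
    n_swaps_per_edge: int = 10,
    seed: int = 0,
    weighted: bool = True,
) -> tuple[SparsityGrid, pd.DataFrame]:
    """Select the sparsity range satisfying the two network-quality criteria.

    A grid point S qualifies when, for every subject, (1) the mean nodal
    degree 2K/N of the thresholded network exceeds 2*ln(N) and (2) the
    small-worldness sigma exceeds ``sigma_min``.  Returns the maximal
    contiguous qualifying sub-grid together with a per-S diagnostics table
    (mean degree, the degree bound, min sigma across subjects).

    Raises :class:`EmptyRangeError` with the diagnostics attached when no
    point qualifies.
    """
    from .graph_metrics import normalized_globals, random_reference

    if candidate is None:
        candidate = SparsityGrid(0.01, 0.50, 0.01)
    n = cohort.atlas.n
    degree_bound = 2.0 * np.log(n)
    s_values = candidate.values
    rows = []
    rng = np.random.default_rng(seed)
    for s in s_values:
        k = edge_count(n, s)
        mean_degree = 2.0 * k / n
        row = {
            "sparsity": s,
            "mean_degree": mean_degree,
            "degree_bound": degree_bound,
            "degree_ok": mean_degree > degree_bound,
            "min_sigma": np.nan,
            "sigma_ok": False,
        }
        if row["degree_ok"]:
            # sigma is the expensive criterion; only evaluate where degree passes
            sigmas = []
            for mat in cohort.matrices:
                net = apply_sparsity(mat, s, weighted=weighted)
                sub_seed = int(rng.integers(0, 2**31 - 1))
                refs = random_reference(net, n_rand, n_swaps_per_edge, seed=sub_seed)
                sigmas.append(normalized_globals(net, refs).sigma)
            row["min_sigma"] = float(np.min(sigmas))
            row["sigma_ok"] = bool(row["min_sigma"] > sigma_min)
        rows.append(row)
    diag = pd.DataFrame(rows)
    ok = (diag["degree_ok"] & diag["sigma_ok"]).to_numpy()
    if not ok.any():
        raise EmptyRangeError(
            "no sparsity level satisfies both the mean-degree and the "
            f"small-worldness (> {sigma_min}) criteria",
            diagnostics=diag,
        )
    # maximal contiguous run of qualifying grid points
    best_start, best_len, cur_start = 0, 0, None
    for i, flag in enumerate(np.append(ok, False)):
        if flag and cur_start is None:
            cur_start = i
        elif not flag and cur_start is not None:
            if i - cur_start > best_len:
                best_start, best_len = cur_start, i - cur_start
            cur_start = None
    sel = s_values[best_start : best_start + best_len]
    grid = SparsityGrid(float(sel[0]), float(sel[-1]), candidate.step) if len(sel) > 1 else \
        SparsityGrid(float(sel[0]), float(sel[0]) + candidate.step, candidate.step)
    return grid, diag
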
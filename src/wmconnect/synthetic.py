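"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a two-group diffusion-MRI connectome study: a shared
modular small-world backbone of FA-like weights; per-subject weight jitter;
a fractional reduction of within-module weights in patients (which drives
clustering and small-worldness down); an additively weakened connected
subnetwork in patients (the target of the network-based statistic); and a
set of edges whose weights shift in fast-progressing patients (the target of
the outcome classifier).  Clinical covariates are drawn to match a typical
sporadic-ALS sample: ages ~ N(49.8, 8^2), disease durations lognormal with
mean ~10.6 months, and functional-scale totals constructed so that computed
progression rates straddle the 0.68/month fast/slow cut-off.

Module membership is assigned round-robin over node indices, so the design
is deterministic and atlas-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataio import Cohort, ConnectivityMatrix, NodeAtlas, SubjectRecord, default_atlas
from .exceptions import ConfigError, SimulationError
from .thresholding import apply_sparsity

Edge = tuple[int, int]


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic cohort.

    Weight parameters are on the FA scale (unitless, bounded in (0, 1)).
    ``group_effect`` multiplies patient within-module weights by
    ``1 - group_effect``; ``nbs_effect`` is an additive reduction on the
    planted connected subnetwork in patients; ``pred_effect`` an additive
    reduction on the predictive edges in fast progressors.
    """

    seed: int = 0
    n_nodes: int = 90
    n_controls: int = 100
    n_patients: int = 73
    n_modules: int = 6
    p_within: float = 0.95
    p_between: float = 0.30
    weight_mean: float = 0.50      # within-module edges
    weight_mean_between: float = 0.35
    weight_sd: float = 0.10
    subject_noise_sd: float = 0.03
    group_effect: float = 0.15
    nbs_edges: tuple[Edge, ...] | None = None   # None -> planted 5-edge path
    nbs_effect: float = 0.10
    pred_edges: tuple[Edge, ...] | None = None  # None -> 20 planted edges
    pred_effect: float = 0.045
    frac_fast: float = 0.40
    rate_cutoff: float = 0.68
    #: sparsest level at which the backbone must stay connected
    min_analysis_sparsity: float = 0.10

    def __post_init__(self):
        for name in ("p_within", "p_between"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        for name in ("group_effect", "nbs_effect", "pred_effect"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0 < self.frac_fast < 1:
            raise ConfigError(f"frac_fast={self.frac_fast} must be in (0, 1)")
        if self.n_nodes < 3 * self.n_modules:
            raise ConfigError("need at least 3 nodes per module")


def module_assignment(n_nodes: int, n_modules: int) -> np.ndarray:
    """Round-robin module labels: node i belongs to module i % n_modules."""
    return np.arange(n_nodes) % n_modules


@dataclass
class Backbone:
    """The shared template: weights, module labels and planted edge sets."""

    template: ConnectivityMatrix
    modules: np.ndarray
    within_mask: np.ndarray     # boolean N x N, True on within-module backbone edges
    nbs_edges: tuple[Edge, ...]
    pred_edges: tuple[Edge, ...]


def _default_planted_edges(
    edge_present: np.ndarray, modules: np.ndarray, rng: np.random.Generator
) -> tuple[tuple[Edge, ...], tuple[Edge, ...]]:
    """Pick a connected 5-edge path (NBS target) and 20 predictive edges from
    the backbone edge set."""
    n = edge_present.shape[0]
    # connected path: greedily walk along present edges starting from node 0's module
    path = [0]
    nbs_edges: list[Edge] = []
    node = 0
    used = {0}
    while len(nbs_edges) < 5:
        nbrs = [j for j in np.flatnonzero(edge_present[node]) if j not in used]
        if not nbrs:
            raise SimulationError("backbone too sparse to plant a connected subnetwork")
        nxt = int(rng.choice(nbrs))
        nbs_edges.append((node, nxt) if node < nxt else (nxt, node))
        used.add(nxt)
        node = nxt
    iu, ju = np.nonzero(np.triu(edge_present, 1))
    nbs_set = set(nbs_edges)
    candidates = [
        (int(i), int(j)) for i, j in zip(iu, ju) if (int(i), int(j)) not in nbs_set
    ]
    idx = rng.choice(len(candidates), size=20, replace=False)
    pred_edges = tuple(candidates[i] for i in sorted(idx))
    return tuple(nbs_edges), pred_edges


def generate_backbone(config: SimulationConfig) -> Backbone:
    """Draw the shared modular weighted template.

    Within-module edges appear with ``p_within`` and carry higher mean weight
    than between-module edges (``p_between``), so sparsity thresholding
    preferentially retains the modular, highly clustered core — a
    small-world topology with sigma > 1.1 at typical analysis sparsities.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_nodes
    modules = module_assignment(n, config.n_modules)
    same = modules[:, None] == modules[None, :]
    iu, ju = np.triu_indices(n, 1)
    within = same[iu, ju]
    p = np.where(within, config.p_within, config.p_between)
    present = rng.random(len(iu)) < p
    mean = np.where(within, config.weight_mean, config.weight_mean_between)
    w = _truncated_normal(rng, mean, config.weight_sd, size=len(iu))
    w[~present] = 0.0

    weights = np.zeros((n, n))
    weights[iu, ju] = w
    weights[ju, iu] = w
    template = ConnectivityMatrix(subject_id="template", weights=weights)

    edge_present = np.zeros((n, n), dtype=bool)
    edge_present[iu, ju] = present
    edge_present |= edge_present.T

    # the analysis assumes the network stays connected at the sparsest level
    s0 = config.min_analysis_sparsity
    net = apply_sparsity(template, s0, weighted=False)
    from scipy.sparse.csgraph import connected_components

    n_comp, _ = connected_components(net.binary, directed=False)
    if n_comp != 1:
        raise SimulationError(
            f"backbone disconnected at S={s0} ({n_comp} components); "
            "increase p_between or module sizes"
        )

    within_mask = np.zeros((n, n), dtype=bool)
    wi = within & present
    within_mask[iu[wi], ju[wi]] = True
    within_mask |= within_mask.T

    nbs_edges, pred_edges = (config.nbs_edges, config.pred_edges)
    if nbs_edges is None or pred_edges is None:
        auto_nbs, auto_pred = _default_planted_edges(edge_present, modules, rng)
        nbs_edges = auto_nbs if nbs_edges is None else nbs_edges
        pred_edges = auto_pred if pred_edges is None else pred_edges
    _check_planted(nbs_edges, edge_present, "nbs_edges", require_connected=True)
    _check_planted(pred_edges, edge_present, "pred_edges", require_connected=False)
    return Backbone(
        template=template, modules=modules, within_mask=within_mask,
        nbs_edges=tuple(nbs_edges), pred_edges=tuple(pred_edges),
    )


def _check_planted(edges, edge_present, name, require_connected):
    for i, j in edges:
        if not edge_present[i, j]:
            raise ConfigError(f"{name}: edge ({i}, {j}) not in the backbone")
    if require_connected and len(edges) > 0:
        nodes = sorted({v for e in edges for v in e})
        index = {v: k for k, v in enumerate(nodes)}
        adj = np.zeros((len(nodes), len(nodes)), dtype=bool)
        for i, j in edges:
            adj[index[i], index[j]] = adj[index[j], index[i]] = True
        from scipy.sparse.csgraph import connected_components

        n_comp, _ = connected_components(adj, directed=False)
        if n_comp != 1:
            raise ConfigError(f"{name} must form a connected subgraph")


def _truncated_normal(rng, mean, sd, size, lo=1e-4, hi=1.0 - 1e-4):
    """Normal draws clipped into (0, 1); FA is bounded, the tails are tiny."""
    return np.clip(rng.normal(mean, sd, size=size), lo, hi)


# ---------------------------------------------------------------------------
# clinical covariates
# ---------------------------------------------------------------------------

def _draw_patient_clinical(rng: np.random.Generator, fast: bool, cutoff: float) -> dict:
    """Duration, functional scores and a fast/slow progression rate.

    The rate is drawn away from the cut-off (slow: 0.1-0.55, fast:
    0.80-2.0 per month) and the scale total is back-computed as
    48 - rate * duration, so the published rate formula is exercised
    end-to-end and integer rounding cannot flip the class.
    """
    # lognormal matched to mean 10.58, sd 5.86 months
    sigma2 = np.log(1 + (5.86 / 10.58) ** 2)
    duration = float(rng.lognormal(np.log(10.58) - sigma2 / 2, np.sqrt(sigma2)))
    duration = min(max(duration, 2.0), 36.0)
    if fast:
        rate = rng.uniform(max(0.80, cutoff + 0.12), 2.0)
    else:
        rate = rng.uniform(0.10, min(0.55, cutoff - 0.13))
    deficit = int(round(rate * duration))
    # integer rounding of the scale total must not flip the class
    if fast:
        deficit = max(deficit, int(np.ceil((cutoff + 0.05) * duration)))
    else:
        deficit = max(min(deficit, int(np.floor((cutoff - 0.05) * duration))), 1)
    deficit = min(deficit, 30)
    alsfrs = 48 - deficit
    # respiratory typically preserved at baseline; split the deficit over
    # bulbar (max 12) and motor (max 24)
    bulbar_def = min(int(round(deficit * 0.25)), 11)
    motor_def = min(deficit - bulbar_def, 23)
    bulbar_def = deficit - motor_def
    respiratory = 12
    return {
        "duration_months": round(duration, 2),
        "alsfrs_r": alsfrs,
        "bulbar": 12 - bulbar_def,
        "motor": 24 - motor_def,
        "respiratory": respiratory,
        "anxiety": float(np.clip(rng.normal(4.1, 5.2), 0, 40).round(1)),
        "depression": float(np.clip(rng.normal(7.2, 7.2), 0, 50).round(1)),
    }


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimulationConfig, atlas: NodeAtlas | None = None) -> Cohort:
    """Generate a full cohort (matrices + metadata) from one seed.

    Identical configs produce identical cohorts.  Patients get within-module
    weights scaled by ``1 - group_effect`` and the planted subnetwork reduced
    by ``nbs_effect``; fast-labelled patients additionally have the
    predictive edges reduced by ``pred_effect``.  Per-subject Gaussian jitter
    of sd ``subject_noise_sd`` is added on backbone edges.
    """
    backbone = generate_backbone(config)
    n = config.n_nodes
    if atlas is None:
        atlas = default_atlas() if n == 90 else NodeAtlas(
            tuple(f"region_{i:03d}" for i in range(n))
        )
    if atlas.n != n:
        raise ConfigError(f"atlas has {atlas.n} nodes but config.n_nodes={n}")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2**20]))

    base = backbone.template.weights
    present = base > 0
    iu, ju = np.triu_indices(n, 1)
    pres_u = present[iu, ju]

    n_fast = int(round(config.frac_fast * config.n_patients))
    if not 0 < n_fast < config.n_patients:
        raise ConfigError("frac_fast leaves no subjects in one progression class")
    fast_flags = np.zeros(config.n_patients, dtype=bool)
    fast_flags[rng.choice(config.n_patients, size=n_fast, replace=False)] = True

    matrices: list[ConnectivityMatrix] = []
    records: list[SubjectRecord] = []

    def build_matrix(sid: str, patient: bool, fast: bool) -> ConnectivityMatrix:
        w = base.copy()
        if patient:
            w[backbone.within_mask] *= 1.0 - config.group_effect
            for i, j in backbone.nbs_edges:
                w[i, j] = w[j, i] = max(w[i, j] - config.nbs_effect, 1e-4)
            if fast:
                for i, j in backbone.pred_edges:
                    w[i, j] = w[j, i] = max(w[i, j] - config.pred_effect, 1e-4)
        noise = rng.normal(0.0, config.subject_noise_sd, size=len(iu))
        wu = w[iu, ju]
        wu = np.where(pres_u, np.clip(wu + noise, 1e-4, 1.0 - 1e-4), 0.0)
        out = np.zeros_like(w)
        out[iu, ju] = wu
        out[ju, iu] = wu
        return ConnectivityMatrix(subject_id=sid, weights=out)

    def motion():
        return np.abs(rng.normal([0.3, 0.3, 0.3, 0.2, 0.2, 0.2, 0.15, 0.1],
                                 [0.15, 0.15, 0.15, 0.1, 0.1, 0.1, 0.05, 0.04]))

    for k in range(config.n_patients):
        sid = f"als{k:03d}"
        fast = bool(fast_flags[k])
        clin = _draw_patient_clinical(rng, fast, config.rate_cutoff)
        matrices.append(build_matrix(sid, patient=True, fast=fast))
        records.append(
            SubjectRecord(
                subject_id=sid, group="patient",
                age=float(np.clip(rng.normal(49.8, 8.0), 25, 75).round(1)),
                sex=int(rng.random() < 40 / 73),
                education=float(np.clip(rng.normal(9.0, 3.2), 0, 20).round(1)),
                motion=motion(), **clin,
            )
        )
    for k in range(config.n_controls):
        sid = f"con{k:03d}"
        matrices.append(build_matrix(sid, patient=False, fast=False))
        records.append(
            SubjectRecord(
                subject_id=sid, group="control",
                age=float(np.clip(rng.normal(49.8, 8.7), 25, 75).round(1)),
                sex=int(rng.random() < 43 / 100),
                education=float(np.clip(rng.normal(8.9, 4.1), 0, 20).round(1)),
                motion=motion(),
            )
        )
    return Cohort(atlas=atlas, matrices=matrices, records=records)


def null_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A cohort with no planted effects of any kind (for validity checks)."""
    return SimulationConfig(
        seed=seed, group_effect=0.0, nbs_effect=0.0, pred_effect=0.0, **overrides
    )
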
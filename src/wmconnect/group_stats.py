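"""Permutation-based group comparison and clinical correlations.

The between-group statistic is the pooled-variance two-sample t on the AUC
values; its null distribution is built by relabeling group membership.  The
permutation p-value uses the add-one estimator
p = (1 + #{|t_perm| >= |t_obs|}) / (n_perm + 1), which can never return 0 and
is valid for a finite number of permutations.  When covariates are supplied
the values are first residualized on them (Freedman-Lane style) and the
residuals are permuted.

Nodal findings follow a two-of-three reporting rule: a region is reported
only when at least two of its three centralities (degree, betweenness,
efficiency) differ significantly between groups in the same direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigError, ValidationError


@dataclass(frozen=True)
class PermutationTestResult:
    metric_name: str
    t_stat: float
    p_perm: float
    n_perm: int
    direction: int  # sign of (group A mean - group B mean)

    def to_dict(self) -> dict:
        return {
            "metric_name": self.metric_name, "t_stat": self.t_stat,
            "p_perm": self.p_perm, "n_perm": self.n_perm, "direction": self.direction,
        }


@dataclass(frozen=True)
class NodalFinding:
    """A region passing the two-of-three rule."""

    node: int
    node_name: str
    measures_significant: tuple[str, ...]
    direction: int
    p_values: dict

    def to_dict(self) -> dict:
        return {
            "node": self.node, "node_name": self.node_name,
            "measures_significant": list(self.measures_significant),
            "direction": self.direction, "p_values": self.p_values,
        }


@dataclass(frozen=True)
class PartialCorrelationResult:
    x_name: str
    y_name: str
    covariate_names: tuple[str, ...]
    r: float
    p: float
    n: int

    def to_dict(self) -> dict:
        return {
            "x_name": self.x_name, "y_name": self.y_name,
            "covariate_names": list(self.covariate_names),
            "r": self.r, "p": self.p, "n": self.n,
        }


def _pooled_t(sum_a, ssq_a, n_a, sum_b, ssq_b, n_b):
    """Two-sample pooled-variance t from group sums and sums of squares.

    Vectorized over leading axes; zero pooled variance yields t = 0.
    """
    mean_a = sum_a / n_a
    mean_b = sum_b / n_b
    var_a = (ssq_a - n_a * mean_a**2) / (n_a - 1)
    var_b = (ssq_b - n_b * mean_b**2) / (n_b - 1)
    sp2 = ((n_a - 1) * var_a + (n_b - 1) * var_b) / (n_a + n_b - 2)
    se = np.sqrt(sp2 * (1 / n_a + 1 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (mean_a - mean_b) / np.where(se > 0, se, 1), 0.0)
    return t


def residualize(values: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Residuals of ``values`` after OLS on [1, covariates]."""
    x = np.column_stack([np.ones(len(values)), np.asarray(covariates, dtype=float)])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValidationError("covariate matrix is rank deficient (collinear columns)")
    beta, *_ = np.linalg.lstsq(x, values, rcond=None)
    return values - x @ beta


def permutation_test(
    values_a: np.ndarray,
    values_b: np.ndarray,
    n_perm: int = 10_000,
    seed: int = 0,
    covariates: np.ndarray | None = None,
    metric_name: str = "",
) -> PermutationTestResult:
    """Two-sample permutation test on the pooled-variance t statistic.

    ``covariates``, if given, is an (n_a + n_b) x k matrix (rows ordered A
    then B); both groups are residualized on it before permuting.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ConfigError("both groups must be nonempty")
    if n_perm < 100:
        raise ConfigError(f"n_perm={n_perm} < 100 gives a uselessly coarse p-value")
    pooled = np.concatenate([a, b])
    if covariates is not None:
        pooled = residualize(pooled, covariates)
    n_a, n_b = len(a), len(b)
    n = n_a + n_b
    if np.allclose(pooled, pooled[0]):
        warnings.warn("degenerate data: zero variance; p = 1", stacklevel=2)
        return PermutationTestResult(metric_name, 0.0, 1.0, n_perm, 0)

    t_obs = float(_pooled_t(
        pooled[:n_a].sum(), (pooled[:n_a] ** 2).sum(), n_a,
        pooled[n_a:].sum(), (pooled[n_a:] ** 2).sum(), n_b,
    ))
    rng = np.random.default_rng(seed)
    total = pooled.sum()
    total_sq = (pooled**2).sum()
    # vectorized relabeling: each row of idx is a permutation's group-A members
    idx = np.argsort(rng.random((n_perm, n)), axis=1)[:, :n_a]
    perm_vals = pooled[idx]
    sum_a = perm_vals.sum(axis=1)
    ssq_a = (perm_vals**2).sum(axis=1)
    t_perm = _pooled_t(sum_a, ssq_a, n_a, total - sum_a, total_sq - ssq_a, n_b)
    p = (1 + np.count_nonzero(np.abs(t_perm) >= abs(t_obs))) / (n_perm + 1)
    return PermutationTestResult(
        metric_name=metric_name, t_stat=t_obs, p_perm=float(p), n_perm=n_perm,
        direction=int(np.sign(t_obs)),
    )


def compare_global(
    auc_table: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int = 0,
    covariates: pd.DataFrame | np.ndarray | None = None,
    metrics: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Patient-vs-control permutation test for each global-metric AUC column.

    ``auc_table`` must have a ``group`` column; every other numeric column is
    tested (raw p-values, no multiplicity correction).  Returns a DataFrame
    with columns metric, t, p_perm, direction where direction is the sign of
    (patient mean - control mean).
    """
    groups = auc_table["group"].to_numpy()
    is_pat = groups == "patient"
    if metrics is None:
        metrics = tuple(
            c for c in auc_table.columns
            if c not in ("subject_id", "group") and np.issubdtype(auc_table[c].dtype, np.number)
        )
    cov = None
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    for m in metrics:
        vals = auc_table[m].to_numpy(dtype=float)
        cov_m = None
        if cov is not None:
            cov_m = np.concatenate([cov[is_pat], cov[~is_pat]], axis=0)
        res = permutation_test(
            vals[is_pat], vals[~is_pat], n_perm=n_perm,
            seed=int(rng.integers(0, 2**31 - 1)), covariates=cov_m, metric_name=m,
        )
        rows.append({"metric": m, "t": res.t_stat, "p_perm": res.p_perm,
                     "direction": res.direction})
    return pd.DataFrame(rows)


def compare_nodal(
    nodal_aucs: dict[str, pd.DataFrame],
    n_perm: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
    covariates: np.ndarray | None = None,
    fdr: bool = False,
) -> list[NodalFinding]:
    """Two-of-three nodal reporting rule over per-node permutation tests.

    ``nodal_aucs`` maps measure name -> DataFrame (subject rows; group column
    plus one column per region).  A node is reported iff >= 2 measures are
    significant at ``alpha`` with the same direction.  ``fdr=True`` applies
    Benjamini-Hochberg within each measure before the rule (off by default).
    """
    measures = tuple(nodal_aucs)
    any_df = next(iter(nodal_aucs.values()))
    node_names = [c for c in any_df.columns if c not in ("subject_id", "group")]
    is_pat = any_df["group"].to_numpy() == "patient"
    rng = np.random.default_rng(seed)
    p_mat = {}
    d_mat = {}
    for meas in measures:
        df = nodal_aucs[meas]
        ps, ds = [], []
        for name in node_names:
            vals = df[name].to_numpy(dtype=float)
            cov_m = None
            if covariates is not None:
                cov = np.asarray(covariates, dtype=float)
                cov_m = np.concatenate([cov[is_pat], cov[~is_pat]], axis=0)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = permutation_test(
                    vals[is_pat], vals[~is_pat], n_perm=n_perm,
                    seed=int(rng.integers(0, 2**31 - 1)), covariates=cov_m,
                    metric_name=f"{meas}:{name}",
                )
            ps.append(res.p_perm)
            ds.append(res.direction)
        ps = np.array(ps)
        if fdr:
            ps = _bh_adjust(ps)
        p_mat[meas] = ps
        d_mat[meas] = np.array(ds)

    findings = []
    for i, name in enumerate(node_names):
        sig = [m for m in measures if p_mat[m][i] < alpha]
        if len(sig) < 2:
            continue
        dirs = {int(d_mat[m][i]) for m in sig}
        # the rule requires a shared direction among the significant measures;
        # keep the largest same-direction subset
        for d in sorted(dirs):
            same = tuple(m for m in sig if d_mat[m][i] == d)
            if len(same) >= 2:
                findings.append(
                    NodalFinding(
                        node=i, node_name=name, measures_significant=same,
                        direction=d,
                        p_values={m: float(p_mat[m][i]) for m in measures},
                    )
                )
                break
    return findings


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(ranked, 1.0)
    return out


def partial_correlation(
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    x_name: str = "x",
    y_name: str = "y",
    covariate_names: tuple[str, ...] = (),
) -> PartialCorrelationResult:
    """Partial Pearson correlation of x and y controlling for covariates.

    Both variables are residualized on [1, covariates] by OLS; r is the
    Pearson correlation of the residuals and p comes from the t distribution
    with n - k - 2 degrees of freedom (k = number of covariates).  An empty
    covariate set reduces to the plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ConfigError("x and y must be 1-D arrays of equal length")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValidationError("missing values in x or y")
    n = len(x)
    if covariates is None or (hasattr(covariates, "size") and covariates.size == 0):
        k = 0
        rx, ry = x - x.mean(), y - y.mean()
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        k = cov.shape[1]
        if n <= k + 2:
            raise ConfigError(f"n={n} too small for {k} covariates")
        rx = residualize(x, cov)
        ry = residualize(y, cov)
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        warnings.warn("zero residual variance; r undefined, returning 0", stacklevel=2)
        r = 0.0
    else:
        r = float((rx * ry).sum() / denom)
    r = max(min(r, 1.0), -1.0)
    df = n - k - 2
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1 - r**2))
        p = float(2 * stats.t.sf(abs(t), df))
    return PartialCorrelationResult(
        x_name=x_name, y_name=y_name, covariate_names=tuple(covariate_names),
        r=r, p=p, n=n,
    )


def clinical_correlations(
    auc_table: pd.DataFrame,
    records: list,
    metrics: tuple[str, ...],
    clinical_vars: tuple[str, ...] = ("alsfrs_r", "bulbar", "motor", "respiratory",
                                     "anxiety", "depression"),
    covariate_fields: tuple[str, ...] = ("age", "sex", "duration_months"),
) -> pd.DataFrame:
    """Partial correlations of patient metric AUCs with clinical scores,
    controlling for age, sex and illness duration by default."""
    recs = {r.subject_id: r for r in records}
    pat = auc_table[auc_table["group"] == "patient"]
    cov = np.array(
        [[getattr(recs[sid], f) for f in covariate_fields] for sid in pat["subject_id"]],
        dtype=float,
    )
    rows = []
    for metric in metrics:
        x = pat[metric].to_numpy(dtype=float)
        for var in clinical_vars:
            y = np.array([getattr(recs[sid], var) for sid in pat["subject_id"]], dtype=float)
            if np.isnan(y).any():
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = partial_correlation(
                    x, y, cov, x_name=metric, y_name=var,
                    covariate_names=covariate_fields,
                )
            rows.append({"metric": metric, "clinical": var, "r": res.r,
                         "p": res.p, "n": res.n})
    return pd.DataFrame(rows)
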
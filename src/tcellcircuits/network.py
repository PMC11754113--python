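"""Pseudobulk aggregation, NB Wald differential expression, and regulator networks.

Differential expression follows the standard RNA-seq negative-binomial
log-linear model: raw counts are summed per (target, donor, condition)
unit, size factors are estimated by median-of-ratios, a per-gene NB GLM
with group and donor terms is fitted by IRLS, and the group coefficient is
tested with a Wald z statistic and BH correction.  Per-gene dispersions are
method-of-moments estimates from GLM residuals, shrunk toward a lowess
mean-dispersion trend (a few pseudo-degrees of freedom of prior weight,
floored at a tenth of the trend) — small designs leave very few residual
degrees of freedom, and unshrunk estimates produce anticonservative Wald
tests.  No log-fold-change shrinkage is applied and exact parity with any
particular external DE package is not claimed.

Directed state-specific networks connect perturbed regulators: an edge
A → B exists when gene B (itself in the perturbed-regulator set) is
differentially expressed (adjusted p < alpha) upon perturbation of A.
Regulation sign is the negation of the observed log2FC: B falling when A is
perturbed means A promotes B.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import networkx as nx
import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

LN2 = np.log(2.0)
MIN_DISP = 1e-8


@dataclass
class Pseudobulk:
    """Per-(target, donor, condition) summed raw counts from single cells."""

    counts: pd.DataFrame          # genes × units (integer sums)
    meta: pd.DataFrame            # per unit: target, donor, condition, n_cells
    dropped: list[str] = field(default_factory=list)


@dataclass
class DEResult:
    """Per-gene NB Wald test results."""

    table: pd.DataFrame           # index gene: base_mean, log2fc, se, p, padj
    excluded: list[str] = field(default_factory=list)
    contrast: tuple[str, str] | None = None

    def significant(self, alpha: float = 0.05) -> pd.Index:
        return self.table.index[self.table["padj"] < alpha]


@dataclass
class RegulatoryNetwork:
    """Directed perturbation network over the regulator set."""

    graph: nx.DiGraph
    edges: pd.DataFrame           # source, sink, sign, log2fc, padj, self_edge
    roles: dict[str, str]

    def degree_summary(self) -> pd.DataFrame:
        nodes = sorted(self.graph.nodes)
        return pd.DataFrame({
            "in_degree": [self.graph.in_degree(n) for n in nodes],
            "out_degree": [self.graph.out_degree(n) for n in nodes],
            "role": [self.roles.get(n, "") for n in nodes],
        }, index=pd.Index(nodes, name="gene"))


def pseudobulk(adata: ad.AnnData, min_cells: int = 10) -> Pseudobulk:
    """Sum raw counts per (target, donor, condition) unit.

    Units with fewer than ``min_cells`` cells are dropped and reported.
    """
    if adata.n_obs == 0:
        raise ValueError("empty matrix")
    X = np.asarray(adata.X)
    obs = adata.obs
    cols, meta_rows, dropped = {}, [], []
    for (target, donor, condition), grp in obs.groupby(
            ["target", "donor", "condition"], observed=True, sort=True):
        unit = f"{target}|{donor}|{condition}"
        n = len(grp)
        if n < min_cells:
            dropped.append(unit)
            continue
        ix = obs.index.get_indexer(grp.index)
        cols[unit] = X[ix].sum(axis=0).astype(np.int64)
        meta_rows.append((unit, target, donor, condition, n))
    counts = pd.DataFrame(cols, index=adata.var_names)
    meta = pd.DataFrame(meta_rows, columns=["unit", "target", "donor", "condition", "n_cells"])
    meta = meta.set_index("unit")
    return Pseudobulk(counts=counts, meta=meta, dropped=dropped)


# ---------------------------------------------------------------------------
# NB GLM machinery
# ---------------------------------------------------------------------------

def size_factors_median_of_ratios(counts: pd.DataFrame) -> pd.Series:
    """DESeq-style size factors: median per sample of ratios to the per-gene
    geometric mean, over genes positive in every sample."""
    log_counts = np.log(counts.where(counts > 0))
    log_gm = log_counts.mean(axis=1)
    usable = np.isfinite(log_gm)
    if not usable.any():
        raise ValueError("no gene is positive in every sample; cannot estimate size factors")
    log_ratios = log_counts.loc[usable].sub(log_gm[usable], axis=0)
    sf = np.exp(log_ratios.median(axis=0))
    return sf / np.exp(np.log(sf).mean())


def _irls_nb(y: np.ndarray, X: np.ndarray, offset: np.ndarray, alpha: float,
             max_iter: int = 50, tol: float = 1e-10, ridge: float = 1e-8
             ) -> tuple[np.ndarray, np.ndarray]:
    """Fit an NB log-linear model; returns (beta, covariance of beta)."""
    n, p = X.shape
    beta = np.zeros(p)
    beta[0] = np.log(max(np.mean(y / np.exp(offset)), 1e-8))
    mu = np.exp(np.clip(X @ beta + offset, -30, 30))
    for _ in range(max_iter):
        w = mu / (1.0 + alpha * mu)
        z = (X @ beta) + (y - mu) / np.maximum(mu, 1e-12)
        XtW = X.T * w
        A = XtW @ X + ridge * np.eye(p)
        b = XtW @ z
        new_beta = np.linalg.solve(A, b)
        new_beta = np.clip(new_beta, -30, 30)
        if np.max(np.abs(new_beta - beta)) < tol:
            beta = new_beta
            break
        beta = new_beta
        mu = np.exp(np.clip(X @ beta + offset, -30, 30))
    mu = np.exp(np.clip(X @ beta + offset, -30, 30))
    w = mu / (1.0 + alpha * mu)
    A = (X.T * w) @ X + ridge * np.eye(p)
    cov = np.linalg.inv(A)
    return beta, cov


def _dispersion_mom(y: np.ndarray, mu: np.ndarray, n_params: int) -> float:
    """Method-of-moments dispersion given fitted means."""
    dof = max(len(y) - n_params, 1)
    num = np.sum(((y - mu) ** 2 - mu) / np.maximum(mu, 1e-12) ** 2)
    return max(num / dof, MIN_DISP)


def _dispersion_trend(base_mean: np.ndarray, disp: np.ndarray) -> np.ndarray:
    """Lowess-smoothed mean–dispersion trend evaluated at each gene."""
    ok = (base_mean > 0) & (disp > MIN_DISP)
    if ok.sum() < 10:
        return np.full_like(disp, np.median(disp[ok]) if ok.any() else MIN_DISP)
    x = np.log(base_mean[ok])
    yv = np.log(disp[ok])
    sm = lowess(yv, x, frac=0.5, return_sorted=True)
    trend = np.interp(np.log(np.maximum(base_mean, 1e-12)), sm[:, 0], sm[:, 1])
    return np.exp(trend)


def nb_wald_de(
    counts: pd.DataFrame,
    group: pd.Series,
    contrast: tuple[str, str],
    donor: pd.Series | None = None,
    size_factors: pd.Series | None = None,
    dispersion: float | None = None,
) -> DEResult:
    """NB Wald differential expression of ``contrast = (test, reference)``.

    ``counts``: genes × samples raw integers.  ``group`` and ``donor`` label
    the sample columns.  Genes with all-zero counts are excluded and
    reported.  log2FC is the group coefficient of the NB GLM (test vs
    reference) on the log2 scale; p-values are Wald normal two-sided with
    BH correction across tested genes.  Passing ``dispersion`` fixes a
    common dispersion for all genes (0 gives the Poisson limit) instead of
    the MoM/trend estimate.
    """
    test_level, ref_level = contrast
    samples = [s for s in counts.columns if group.get(s) in (test_level, ref_level)]
    if not samples:
        raise ValueError(f"no samples for contrast {contrast}")
    sub = counts[samples]
    g = group.reindex(samples)
    if (g == test_level).sum() == 0 or (g == ref_level).sum() == 0:
        raise ValueError(f"both contrast groups must be non-empty: {contrast}")
    vals = sub.to_numpy(float)
    frac = vals != np.floor(vals)
    if frac.any():
        raise ValueError("counts must be integers")

    cols = [np.ones(len(samples)), (g == test_level).to_numpy(float)]
    names = ["intercept", "group"]
    if donor is not None:
        d = donor.reindex(samples)
        levels = sorted(d.unique())
        if len(levels) < 2:
            raise ValueError("donor covariate requested with a single donor")
        for lev in levels[1:]:
            cols.append((d == lev).to_numpy(float))
            names.append(f"donor_{lev}")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank-deficient (confounded group/donor)")

    if size_factors is None:
        size_factors = size_factors_median_of_ratios(sub)
    sf = size_factors.reindex(samples).to_numpy(float)
    offset = np.log(sf)

    nonzero = sub.sum(axis=1) > 0
    excluded = sub.index[~nonzero].tolist()
    tested = sub.index[nonzero]
    Y = sub.loc[tested].to_numpy(float)
    norm = Y / sf
    base_mean = norm.mean(axis=1)

    betas = np.empty((len(tested), X.shape[1]))
    if dispersion is not None:
        disp_final = np.full(len(tested), max(dispersion, 0.0))
    else:
        # pass 1: moderate-dispersion fit to get mu, then MoM dispersions
        disp_init = 0.1
        disp = np.empty(len(tested))
        for i in range(len(tested)):
            beta, _ = _irls_nb(Y[i], X, offset, disp_init)
            mu = np.exp(np.clip(X @ beta + offset, -30, 30))
            disp[i] = _dispersion_mom(Y[i], mu, X.shape[1])
        trend = _dispersion_trend(base_mean, disp)
        # shrink the noisy per-gene MoM estimate toward the trend with a
        # prior weight of a few pseudo-degrees of freedom, floored at a
        # fraction of the trend
        dof = max(len(samples) - X.shape[1], 1)
        prior_df = 4.0
        shrunk = (dof * disp + prior_df * trend) / (dof + prior_df)
        disp_final = np.maximum(shrunk, 0.1 * trend)

    # pass 2: final fit and Wald test at the stabilized dispersion
    log2fc = np.empty(len(tested))
    se = np.empty(len(tested))
    pvals = np.empty(len(tested))
    for i in range(len(tested)):
        beta, cov = _irls_nb(Y[i], X, offset, disp_final[i])
        betas[i] = beta
        log2fc[i] = beta[1] / LN2
        se_i = np.sqrt(max(cov[1, 1], 0.0))
        se[i] = se_i / LN2
        stat = beta[1] / se_i if se_i > 0 else 0.0
        from scipy.stats import norm as normal
        pvals[i] = 2.0 * normal.sf(abs(stat))
    padj = multipletests(pvals, method="fdr_bh")[1] if len(pvals) else np.array([])
    table = pd.DataFrame({
        "base_mean": base_mean, "log2fc": log2fc, "se": se,
        "dispersion": disp_final, "p": pvals, "padj": padj,
    }, index=tested)
    return DEResult(table=table, excluded=excluded, contrast=contrast)


# ---------------------------------------------------------------------------
# regulator networks
# ---------------------------------------------------------------------------

def assign_roles(per_target: pd.DataFrame, alpha: float = 0.01) -> dict[str, str]:
    """Node roles from activation tests.

    rest_maintenance: knockdown significantly raises activation at rest;
    activation_promoting: knockdown significantly lowers activation when
    stimulated; no_activation_effect otherwise.
    """
    roles: dict[str, str] = {}
    for t in per_target["target"].unique():
        sub = per_target[per_target["target"] == t].set_index("condition")
        role = "no_activation_effect"
        if "rest" in sub.index:
            r = sub.loc["rest"]
            if r["p_adj"] < alpha and r["median_score"] > r["median_nt"]:
                role = "rest_maintenance"
        if role == "no_activation_effect" and "stim" in sub.index:
            s = sub.loc["stim"]
            if s["p_adj"] < alpha and s["median_score"] < s["median_nt"]:
                role = "activation_promoting"
        roles[t] = role
    return roles


def build_network(
    de_by_target: dict[str, DEResult],
    regulator_set: set[str] | list[str],
    roles: dict[str, str],
    alpha: float = 0.05,
) -> RegulatoryNetwork:
    """Directed edges A → B for regulators B responding to perturbation of A.

    Edge sign encodes regulation: B down upon perturbing A (log2FC < 0)
    means A promotes B (sign +1); B up means A represses B (sign −1).
    Self-edges (knockdown altering the perturbed gene's own transcript) are
    allowed but flagged.
    """
    regulators = set(regulator_set)
    missing_roles = [a for a in de_by_target if a not in roles]
    if missing_roles:
        raise ValueError(f"missing role labels for perturbed nodes: {missing_roles[:5]}")
    rows = []
    for source, de in de_by_target.items():
        tab = de.table
        hits = tab.index.intersection(regulators)
        sig = tab.loc[hits][tab.loc[hits, "padj"] < alpha]
        for sink, row in sig.iterrows():
            sign = 1 if row["log2fc"] < 0 else -1
            rows.append((source, sink, sign, float(row["log2fc"]), float(row["padj"]),
                         source == sink))
    edges = pd.DataFrame(rows, columns=["source", "sink", "sign", "log2fc", "padj",
                                        "self_edge"])
    graph = nx.DiGraph()
    graph.add_nodes_from(set(de_by_target) | regulators)
    for _, e in edges.iterrows():
        graph.add_edge(e["source"], e["sink"], sign=int(e["sign"]),
                       log2fc=e["log2fc"], padj=e["padj"])
    return RegulatoryNetwork(graph=graph, edges=edges, roles=dict(roles))
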
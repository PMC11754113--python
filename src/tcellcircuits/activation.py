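"""Per-cell activation scoring from a stimulation-derived gene signature.

The signature is derived from non-targeting (NT) control cells: genes
differentially expressed between stimulated and resting NT cells (|log2FC|
strictly greater than 0.25, detected in at least 10% of stimulated or
resting NT cells) receive a weight GW equal to that log2FC.  GM is the mean
normalized expression of the gene across NT cells of the cell type.  Each
cell's activation score is S = sum over signature genes of GE * GW / GM,
where GE is the cell's normalized expression.  Per-target significance uses
a two-sided Wilcoxon rank-sum test (continuity-corrected normal
approximation) of target-cell scores against NT scores within each
condition, Bonferroni-corrected across targets; adjusted P < 0.01 is called
significant.

Normalization here is depth scaling to 10,000 counts per cell followed by
log1p; the score is a ratio statistic (GE/GM) and is invariant to common
rescaling of GE and GM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_MIN_ABS_LFC = 0.25
DEFAULT_MIN_DETECT_PCT = 0.10
GM_EPS = 1e-8
NT_LABELS = ("NT", "AAVS1")


@dataclass
class ActivationSignature:
    """Gene weights (stim-vs-rest log2FC in NT cells) and NT control means."""

    table: pd.DataFrame            # index gene: gw, gm, pct_rest, pct_stim, p_wilcoxon
    cell_type: str
    min_abs_lfc: float = DEFAULT_MIN_ABS_LFC
    min_detect_pct: float = DEFAULT_MIN_DETECT_PCT
    dropped_low_gm: list[str] = field(default_factory=list)

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class ActivationScores:
    """Per-cell scores plus per-target rank-sum results per condition."""

    per_cell: pd.Series
    per_target: pd.DataFrame | None = None   # columns: condition, target, median_score,
                                             # median_nt, n_cells, p, p_adj, significant


def passes_signature_thresholds(
    lfc: float,
    pct_rest: float,
    pct_stim: float,
    min_abs_lfc: float = DEFAULT_MIN_ABS_LFC,
    min_detect_pct: float = DEFAULT_MIN_DETECT_PCT,
) -> bool:
    """Signature membership filter: |log2FC| strictly above ``min_abs_lfc``
    and detection in at least ``min_detect_pct`` of rest or stim cells."""
    return abs(lfc) > min_abs_lfc and (pct_rest >= min_detect_pct or pct_stim >= min_detect_pct)


def normalize_expression(adata: ad.AnnData, scale: float = 1e4) -> pd.DataFrame:
    """Depth-scale each cell to ``scale`` total counts, then log1p."""
    X = np.asarray(adata.X, dtype=float)
    totals = X.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return pd.DataFrame(np.log1p(X / totals * scale),
                        index=adata.obs_names, columns=adata.var_names)


def _is_nt(targets: pd.Series) -> pd.Series:
    return targets.isin(NT_LABELS)


def derive_signature(
    adata: ad.AnnData,
    cell_type: str | None = None,
    min_abs_lfc: float = DEFAULT_MIN_ABS_LFC,
    min_detect_pct: float = DEFAULT_MIN_DETECT_PCT,
    min_cells: int = 50,
) -> ActivationSignature:
    """Derive the activation signature from NT control cells.

    log2FC is computed Seurat-style from exponentiated means of the
    normalized expression: log2((mean(expm1 stim) + 1) / (mean(expm1 rest) + 1)).
    Detection means raw count > 0.  Genes with |log2FC| <= min_abs_lfc
    (strict inequality required to pass) or detected in under
    ``min_detect_pct`` of both states are excluded; genes whose NT control
    mean falls at or below a small floor are dropped and reported.
    """
    obs = adata.obs
    if cell_type is not None and "cell_type" in obs:
        adata = adata[obs["cell_type"] == cell_type]
        obs = adata.obs
    nt = adata[_is_nt(obs["target"]).to_numpy()]
    if nt.n_obs == 0:
        raise ValueError("no NT control cells")
    rest = nt[(nt.obs["condition"] == "rest").to_numpy()]
    stim = nt[(nt.obs["condition"] == "stim").to_numpy()]
    if rest.n_obs == 0 or stim.n_obs == 0:
        raise ValueError("both rest and stim NT populations are required")
    if rest.n_obs < min_cells or stim.n_obs < min_cells:
        raise ValueError(
            f"need >= {min_cells} NT cells per state, got rest={rest.n_obs} stim={stim.n_obs}")

    norm_rest = normalize_expression(rest)
    norm_stim = normalize_expression(stim)
    mean_rest = np.expm1(norm_rest).mean(axis=0)
    mean_stim = np.expm1(norm_stim).mean(axis=0)
    lfc = np.log2((mean_stim + 1.0) / (mean_rest + 1.0))

    pct_rest = (np.asarray(rest.X) > 0).mean(axis=0)
    pct_stim = (np.asarray(stim.X) > 0).mean(axis=0)
    lfc_arr = np.asarray(lfc)
    passing = np.array([
        passes_signature_thresholds(l, pr, ps, min_abs_lfc, min_detect_pct)
        for l, pr, ps in zip(lfc_arr, pct_rest, pct_stim)
    ])

    pvals = np.ones(adata.n_vars)
    r = norm_rest.to_numpy()
    s = norm_stim.to_numpy()
    for j in np.flatnonzero(passing):
        if np.ptp(np.concatenate([r[:, j], s[:, j]])) == 0:
            continue
        pvals[j] = stats.mannwhitneyu(s[:, j], r[:, j], alternative="two-sided").pvalue

    gm = normalize_expression(nt).mean(axis=0)
    tab = pd.DataFrame({
        "gw": lfc, "gm": gm, "pct_rest": pct_rest, "pct_stim": pct_stim,
        "p_wilcoxon": pvals,
    }, index=adata.var_names)
    tab = tab[np.asarray(passing)]
    dropped = tab.index[tab["gm"] <= GM_EPS].tolist()
    tab = tab[tab["gm"] > GM_EPS]
    ct = cell_type if cell_type is not None else str(obs.get("cell_type", pd.Series(["all"])).iloc[0])
    return ActivationSignature(table=tab, cell_type=ct, min_abs_lfc=min_abs_lfc,
                               min_detect_pct=min_detect_pct, dropped_low_gm=dropped)


def score_cells(
    adata: ad.AnnData,
    sig: ActivationSignature,
    normalized: pd.DataFrame | None = None,
) -> ActivationScores:
    """Per-cell activation score S = sum_g GE_g * GW_g / GM_g.

    Cells lacking every signature gene (or all-zero cells) score 0.  Pass a
    pre-computed ``normalized`` expression frame to score on an alternative
    normalization.
    """
    if len(sig) == 0:
        raise ValueError("signature is empty")
    if (sig.table["gm"] <= 0).any():
        raise ValueError("signature contains non-positive GM; filter upstream")
    ge = normalize_expression(adata) if normalized is None else normalized
    common = sig.genes.intersection(ge.columns)
    weights = (sig.table.loc[common, "gw"] / sig.table.loc[common, "gm"]).to_numpy()
    scores = ge[common].to_numpy() @ weights if len(common) else np.zeros(len(ge))
    return ActivationScores(per_cell=pd.Series(scores, index=ge.index, name="activation_score"))


def test_perturbations(
    scores: ActivationScores,
    labels: pd.DataFrame,
    alpha: float = 0.01,
    min_cells: int = 10,
) -> ActivationScores:
    """Rank-sum test of each target's scores against NT scores per condition.

    Two-sided Wilcoxon rank-sum with continuity-corrected normal
    approximation, Bonferroni-corrected across targets within each
    condition; significant means adjusted P < ``alpha`` (default 0.01).
    Targets with fewer than ``min_cells`` cells in a condition are skipped.
    """
    df = labels.copy()
    df["score"] = scores.per_cell.reindex(df.index).to_numpy()
    rows = []
    for condition, grp in df.groupby("condition", observed=True, sort=False):
        nt_scores = grp.loc[_is_nt(grp["target"]), "score"].to_numpy()
        if len(nt_scores) == 0:
            raise ValueError(f"no NT cells in condition {condition!r}")
        targets = [t for t in grp["target"].unique() if t not in NT_LABELS]
        cond_rows = []
        for t in targets:
            ts = grp.loc[grp["target"] == t, "score"].to_numpy()
            if len(ts) < min_cells:
                continue
            p = stats.mannwhitneyu(ts, nt_scores, alternative="two-sided",
                                   use_continuity=True, method="asymptotic").pvalue
            cond_rows.append((condition, t, float(np.median(ts)),
                              float(np.median(nt_scores)), len(ts), float(p)))
        m = len(cond_rows)
        for condition_, t, med, med_nt, n, p in cond_rows:
            p_adj = min(1.0, p * m)
            rows.append((condition_, t, med, med_nt, n, p, p_adj, p_adj < alpha))
    per_target = pd.DataFrame(rows, columns=[
        "condition", "target", "median_score", "median_nt", "n_cells", "p", "p_adj",
        "significant"])
    return ActivationScores(per_cell=scores.per_cell, per_target=per_target)
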
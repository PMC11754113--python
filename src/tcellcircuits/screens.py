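"""Sorted-bin CRISPR screen analysis.

A sort-and-sequence screen compares sgRNA abundance between FACS bins of
cells sorted on a surface phenotype (here IL-2Rα).  Positive guide log2 fold
change (low/high bin) means knockout cells accumulate in the phenotype-low
bin, i.e. the targeted gene is a positive regulator.  The gene-level test is
a guide-permutation test on the median guide log2FC, with Benjamini–Hochberg
FDR control within each screen condition; hits are called at FDR < 0.05.
Hits are then classified across conditions as consistent (significant
everywhere, same direction), differential (significant with opposing
directions), or context-specific (significant somewhere but not everywhere,
never opposing).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .io_formats import CTRL_GENE, SampleSheet


@dataclass
class ScreenCounts:
    """sgRNA × sample sorted-bin count table with a guide→gene map."""

    counts: pd.DataFrame          # guides × samples, integer
    guide_map: pd.Series          # guide id → gene symbol (controls → CTRL)
    sheet: SampleSheet

    def __post_init__(self) -> None:
        if not self.sheet.is_screen:
            raise ValueError("screen counts need a sample sheet with sorted bins")
        missing = self.counts.index.difference(self.guide_map.index)
        if len(missing):
            raise ValueError(f"guides without gene mapping: {list(missing[:5])}")
        if list(self.counts.columns) != self.sheet.sample_ids:
            raise ValueError("count columns must follow the sample sheet order")

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.sheet.table["condition"]))


@dataclass
class GuideEffects:
    """Per-guide low/high-bin log2 fold changes.

    ``lfc`` has one row per guide and one column per (condition, donor).
    """

    lfc: pd.DataFrame             # guides × MultiIndex (condition, donor)
    guide_map: pd.Series
    pseudocount: float

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.lfc.columns.get_level_values(0)))


@dataclass
class GeneScreenResult:
    """Gene-level screen statistics for one condition."""

    condition: str
    table: pd.DataFrame           # index gene: median_lfc, p_perm, fdr, n_guides, direction


@dataclass
class RegulatorClassification:
    """Cross-condition regulator categories and summary counts."""

    categories: pd.Series         # gene → category
    per_condition: pd.DataFrame   # MultiIndex columns (condition, significant/direction)
    summary: dict = field(default_factory=dict)


def guide_lfc(counts: ScreenCounts, pseudocount: float = 0.5) -> GuideEffects:
    """Per-guide low/high-bin log2 fold change after per-million normalization.

    lfc = log2((low_cpm + a) / (high_cpm + a)) per (condition, donor), where a
    is the pseudocount.  A guide absent from both bins scores exactly 0.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    totals = counts.counts.sum(axis=0)
    if (totals == 0).any():
        zero = totals.index[int(np.argmax(totals.to_numpy() == 0))]
        raise ValueError(f"sample {zero!r} has zero total reads")
    cpm = counts.counts / totals * 1e6
    sheet = counts.sheet.table
    cols = {}
    for (cond, donor), grp in sheet.groupby(["condition", "donor"], observed=True, sort=False):
        low = grp.loc[grp["bin"] == "low", "sample_id"].iloc[0]
        high = grp.loc[grp["bin"] == "high", "sample_id"].iloc[0]
        cols[(cond, donor)] = np.log2((cpm[low] + pseudocount) / (cpm[high] + pseudocount))
    lfc = pd.DataFrame(cols)
    lfc.columns = pd.MultiIndex.from_tuples(lfc.columns, names=["condition", "donor"])
    return GuideEffects(lfc=lfc, guide_map=counts.guide_map, pseudocount=pseudocount)


def _pooled_values(effects: GuideEffects, condition: str) -> tuple[np.ndarray, pd.Index]:
    """Guide × donor lfc matrix for one condition (guides pooled across donors)."""
    sub = effects.lfc.xs(condition, axis=1, level="condition")
    return sub.to_numpy(float), sub.index


def gene_test(
    effects: GuideEffects,
    n_perm: int = 10_000,
    seed: int | None = 0,
    method: str = "auto",
    max_exhaustive: int = 50_000,
) -> dict[str, GeneScreenResult]:
    """Permutation test of the per-gene median guide log2FC, per condition.

    The statistic is the median of a gene's guide lfc values pooled across
    donors.  The null is built by re-assigning guide identities at random
    (control guides included in the pool): for a gene with k guides, the null
    distribution is the median over k randomly chosen guides' pooled values.
    Two-sided p = (1 + #{|median_perm| >= |median_obs|}) / (1 + n_perm) in
    Monte-Carlo mode; with ``method="exhaustive"`` every C(n, k) guide subset
    is enumerated and p is the exact null fraction.  BH correction is applied
    across genes within each condition.
    """
    if method not in ("auto", "exhaustive", "montecarlo"):
        raise ValueError(f"unknown method {method!r}")
    if method != "exhaustive" and n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    genes_all = effects.guide_map[effects.guide_map != CTRL_GENE]
    counts_per_gene = genes_all.groupby(genes_all).size()
    too_few = counts_per_gene[counts_per_gene < 2]
    if len(too_few):
        raise ValueError(f"genes with < 2 guides: {list(too_few.index[:5])}")

    results: dict[str, GeneScreenResult] = {}
    rng = np.random.default_rng(seed)
    for cond in effects.conditions:
        values, guide_index = _pooled_values(effects, cond)
        n_guides_total = values.shape[0]
        gene_of = effects.guide_map.reindex(guide_index)
        rows = []
        gene_groups = {
            g: np.flatnonzero((gene_of == g).to_numpy())
            for g in counts_per_gene.index
        }
        # shared null per guide-count k (one permutation scheme serves all
        # genes with the same number of guides)
        ks = sorted({len(ix) for ix in gene_groups.values()})
        nulls: dict[int, np.ndarray] = {}
        exhaustive: dict[int, bool] = {}
        from math import comb
        for k in ks:
            n_comb = comb(n_guides_total, k)
            use_exh = method == "exhaustive" or (method == "auto" and n_comb <= max_exhaustive)
            if method == "exhaustive" and n_comb > max_exhaustive:
                raise ValueError(
                    f"exhaustive enumeration infeasible: C({n_guides_total},{k}) = {n_comb}"
                )
            if use_exh:
                meds = np.array([
                    np.median(values[list(sub), :])
                    for sub in itertools.combinations(range(n_guides_total), k)
                ])
            else:
                idx = rng.integers(0, n_guides_total, size=(n_perm, k))
                meds = np.median(values[idx, :].reshape(n_perm, -1), axis=1)
            nulls[k] = np.abs(meds)
            exhaustive[k] = use_exh
        for gene, ix in gene_groups.items():
            obs = float(np.median(values[ix, :]))
            k = len(ix)
            null = nulls[k]
            hits = int((null >= abs(obs) - 1e-12).sum())
            if exhaustive[k]:
                p = hits / len(null)
            else:
                p = (1 + hits) / (1 + len(null))
            rows.append((gene, obs, p, k))
        tab = pd.DataFrame(rows, columns=["gene", "median_lfc", "p_perm", "n_guides"])
        tab = tab.set_index("gene")
        tab["fdr"] = multipletests(tab["p_perm"], method="fdr_bh")[1]
        tab["direction"] = np.sign(tab["median_lfc"]).astype(int)
        results[cond] = GeneScreenResult(condition=cond, table=tab)
    return results


def classify_regulators(
    results: dict[str, GeneScreenResult],
    fdr_threshold: float = 0.05,
) -> RegulatorClassification:
    """Classify genes across screen conditions by significance and direction.

    consistent: significant in all conditions with identical direction;
    differential: significant in >= 2 conditions with opposing directions;
    context_specific: significant somewhere but not everywhere, never
    opposing; non_hit otherwise.
    """
    if len(results) < 2:
        raise ValueError("classification needs >= 2 conditions")
    conds = list(results)
    gene_sets = [set(r.table.index) for r in results.values()]
    genes = sorted(set.union(*gene_sets))
    if any(gs != set(genes) for gs in gene_sets):
        raise ValueError("condition results cover different gene sets")

    sig = pd.DataFrame({c: results[c].table["fdr"] < fdr_threshold for c in conds}).loc[genes]
    direc = pd.DataFrame({c: results[c].table["direction"] for c in conds}).loc[genes]

    cats = []
    for g in genes:
        s = sig.loc[g]
        d = direc.loc[g][s]
        n_sig = int(s.sum())
        if n_sig == 0:
            cats.append("non_hit")
        elif n_sig >= 2 and len(set(d)) > 1:
            cats.append("differential")
        elif n_sig == len(conds):
            cats.append("consistent")
        else:
            cats.append("context_specific")
    categories = pd.Series(cats, index=pd.Index(genes, name="gene"), name="category")

    per_condition = pd.concat(
        {c: pd.DataFrame({"significant": sig[c], "direction": direc[c]}) for c in conds},
        axis=1,
    )
    n_hits_total = int((categories != "non_hit").sum())
    n_all = int(sig.all(axis=1).sum())
    n_consistent = int((categories == "consistent").sum())
    summary = {
        "n_conditions": len(conds),
        "n_hits_total": n_hits_total,
        "n_all_conditions": n_all,
        "n_consistent": n_consistent,
        "n_differential": int((categories == "differential").sum()),
        "n_context_specific": int((categories == "context_specific").sum()),
        "pct_context_dependent": (
            100.0 * (n_hits_total - n_consistent) / n_hits_total if n_hits_total else float("nan")
        ),
    }
    return RegulatorClassification(categories=categories, per_condition=per_condition,
                                   summary=summary)
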
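"""Stimulation-response categorization and downstream statistics on knockout
bulk RNA-seq.

Genes are first catalogued by their stimulation response in control samples
(up / down / ns at adjusted P < 0.05 and |log2FC| > 1, both strict).
Knockout DEGs are then partitioned by that catalog and each responsive
group's knockout log2FCs are compared with the non-responsive group by
Welch's t-test (Bonferroni over the comparisons).  A one-sided binomial
test quantifies aberrant (excess) representation of stimulation-responsive
genes among knockout DEGs, and a one-sided Fisher exact test quantifies
enrichment of screen-identified regulators among knockout DEGs within the
screen-library ∩ expressed universe.  Finally, an activation gene signature
is derived from control stim-vs-rest DE at adjusted P < 0.01, log2FC > 2 and
base mean > 10 (all strict).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .network import DEResult

EXPRESSED_BASE_MEAN = 10.0


@dataclass
class StimResponseCatalog:
    categories: pd.Series         # gene → up / down / ns
    padj_lt: float = 0.05
    abs_lfc_gt: float = 1.0

    def genes(self, category: str) -> pd.Index:
        return self.categories.index[self.categories == category]


@dataclass
class CategoryComparison:
    table: pd.DataFrame           # per category: t, p, p_bonferroni, n, n_ns
    values: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class EnrichmentResult:
    table: np.ndarray             # 2x2 [[deg&reg, deg&non], [nondeg&reg, nondeg&non]]
    odds_ratio: float
    p: float
    universe: dict = field(default_factory=dict)


def stim_catalog(control_de: DEResult, padj_lt: float = 0.05,
                 abs_lfc_gt: float = 1.0) -> StimResponseCatalog:
    """Categorize genes by stimulation response in control samples."""
    t = control_de.table
    up = (t["padj"] < padj_lt) & (t["log2fc"] > abs_lfc_gt)
    down = (t["padj"] < padj_lt) & (t["log2fc"] < -abs_lfc_gt)
    cats = pd.Series("ns", index=t.index, name="stim_response")
    cats[up] = "up"
    cats[down] = "down"
    return StimResponseCatalog(categories=cats, padj_lt=padj_lt, abs_lfc_gt=abs_lfc_gt)


def category_ttest(ko_de: DEResult, catalog: StimResponseCatalog,
                   deg_alpha: float = 0.05) -> CategoryComparison:
    """Welch t-test of each responsive group's KO log2FCs vs the ns group.

    Only knockout DEGs (adjusted p < ``deg_alpha``) enter the groups; the
    Bonferroni multiplier is the number of comparisons performed (up, down).
    """
    degs = ko_de.table[ko_de.table["padj"] < deg_alpha]
    cats = catalog.categories.reindex(degs.index).fillna("ns")
    groups = {c: degs.loc[cats == c, "log2fc"].to_numpy() for c in ("up", "down", "ns")}
    comparisons = [c for c in ("up", "down") if len(groups[c]) >= 2]
    if len(groups["ns"]) < 2:
        raise ValueError("ns group has < 2 members; t-test undefined")
    for c in ("up", "down"):
        if 0 < len(groups[c]) < 2:
            raise ValueError(f"group {c!r} has < 2 members; t-test undefined")
    m = len(comparisons)
    rows = []
    for c in comparisons:
        t, p = stats.ttest_ind(groups[c], groups["ns"], equal_var=False)
        rows.append((c, float(t), float(p), min(1.0, float(p) * m),
                     len(groups[c]), len(groups["ns"])))
    table = pd.DataFrame(rows, columns=["category", "t", "p", "p_bonferroni", "n", "n_ns"])
    return CategoryComparison(table=table.set_index("category"), values=groups)


def binomial_aberrance(ko_de: DEResult, catalog: StimResponseCatalog,
                       deg_alpha: float = 0.05, alternative: str = "greater") -> dict:
    """One-sided binomial test of stimulation-responsive excess among KO DEGs.

    k = responsive KO DEGs, n = all KO DEGs, null p0 = responsive fraction
    among all catalogued (expressed) genes.
    """
    degs = ko_de.table.index[ko_de.table["padj"] < deg_alpha]
    n = len(degs)
    if n == 0:
        raise ValueError("no knockout DEGs; binomial test undefined")
    responsive = catalog.categories.index[catalog.categories != "ns"]
    k = len(degs.intersection(responsive))
    p0 = len(responsive) / len(catalog.categories)
    if p0 == 0.0:
        p = 0.0 if k > 0 else 1.0
    else:
        p = stats.binomtest(k, n, p0, alternative=alternative).pvalue
    return {"k": k, "n": n, "p0": p0, "p": float(p), "alternative": alternative,
            "observed_fraction": k / n}


def regulator_enrichment(ko_de: DEResult, regulators: set[str] | list[str],
                         universe: set[str] | list[str],
                         deg_alpha: float = 0.05) -> EnrichmentResult:
    """One-sided Fisher exact test for regulator over-representation in KO DEGs.

    ``universe`` is the screen-library ∩ expressed gene set; ``regulators``
    must be a subset of it.
    """
    universe = set(universe)
    regulators = set(regulators)
    if not universe:
        raise ValueError("empty universe")
    if not regulators <= universe:
        raise ValueError("regulators must be a subset of the universe")
    degs = set(ko_de.table.index[ko_de.table["padj"] < deg_alpha]) & universe
    non_degs = universe - degs
    a = len(degs & regulators)
    b = len(degs - regulators)
    c = len(non_degs & regulators)
    d = len(non_degs - regulators)
    table = np.array([[a, b], [c, d]])
    odds, p = stats.fisher_exact(table, alternative="greater")
    return EnrichmentResult(table=table, odds_ratio=float(odds), p=float(p),
                            universe={"n_universe": len(universe),
                                      "n_regulators": len(regulators),
                                      "n_non_regulators": len(universe - regulators),
                                      "n_degs": len(degs)})


def signature_genes(de: DEResult, padj_lt: float = 0.01, lfc_gt: float = 2.0,
                    basemean_gt: float = EXPRESSED_BASE_MEAN) -> list[str]:
    """Activation signature gene list from control stim-vs-rest DE.

    All three thresholds are strict inequalities; boundary values are
    excluded.
    """
    t = de.table
    keep = (t["padj"] < padj_lt) & (t["log2fc"] > lfc_gt) & (t["base_mean"] > basemean_gt)
    return t.index[keep].tolist()
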
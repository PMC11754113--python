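# tcellcircuits

Mapping **context-dependent gene regulators in primary human CD4⁺ T cells**.
Effector (T_eff) and regulatory (T_reg) T cells must hold distinct resting
identities yet respond sharply to stimulation, and the *trans*-regulators
controlling markers such as IL-2Rα (CD25) differ between cell types and
activation states.  This package implements, as a tested reusable library
with a thin `tcc` command line, the analysis chain used to chart such
regulators:

- **Sorted-bin CRISPR screens** (`screens`): cells are FACS-sorted into the
  top/bottom 20% by surface phenotype and sgRNA abundance is compared
  between bins.  Per guide, `lfc = log2((low_cpm + α)/(high_cpm + α))`
  (α = 0.5), so positive values mean the knockout lowers the phenotype —
  the gene is a positive regulator.  The gene statistic is the median guide
  lfc pooled across donors, tested by permuting the guide→gene assignment
  (exact enumeration on small instances), with Benjamini–Hochberg FDR per
  condition and hits at FDR < 0.05.  Hits are classified across conditions
  as *consistent*, *differential* (opposing significant directions) or
  *context-specific*.
- **Perturbation activation scoring** (`activation`): an activation
  signature is derived from non-targeting control cells (stim-vs-rest
  |log2FC| > 0.25, detected in ≥ 10% of either state); each cell scores
  S = Σ_g GE·GW/GM, and each target is compared with controls by a
  continuity-corrected Wilcoxon rank-sum test with Bonferroni correction
  (significant at adjusted P < 0.01).
- **Pseudobulk NB differential expression and regulator networks**
  (`network`): raw counts summed per (target, donor, condition); a
  negative-binomial log-linear model with donor covariate, median-of-ratios
  size factors, trend-shrunk method-of-moments dispersions and a Wald test
  (BH-adjusted, α = 0.05); directed edges A → B when regulator B responds
  to perturbing A, signed so that "B falls ⇒ A promotes B".
- **Stimulation-response statistics on knockout bulk RNA-seq** (`bulkstim`):
  response catalog (adj P < 0.05 and |log2FC| > 1), Welch t-tests of
  knockout effects per response category (Bonferroni), a one-sided binomial
  test for aberrant expression of stimulation-specific genes, one-sided
  Fisher enrichment of screen regulators among knockout DEGs, and the CAR
  activation signature filter (adj P < 0.01, log2FC > 2, baseMean > 10).
- **Chromatin arm** (`chromatin`): exogenous spike-in scaling by
  s = (ChIP_primary/ChIP_spike)/(input_primary/input_spike); Poisson
  local-λ peak calling against a knockout background; peak-union
  segmentation into ≤ 5,000 bp regions with NB differential testing and
  nearest-TSS annotation; and the RNA polymerase II pausing index
  PI = (TSS cov/400 bp)/(body cov/body length) with a ±200 bp TSS window
  and +400 bp body offsets, on expressed genes (base mean > 10).
- **Synthetic data** (`synthdata`): cell-level generators for every stage —
  sort-and-sequence screens with planted per-condition effects, NB
  single-cell/bulk counts with donor effects and an activation program, and
  coverage tracks with controllable pausing and a 2.5% spike-in fraction —
  each returning the ground truth it planted.

## Worked example

Simulate a two-condition screen with three planted regulators — one
consistent (β = −2 in both conditions), one differential (β = +2 at rest,
−2 stimulated), one stimulation-specific — then test and classify:

```python
from tcellcircuits import synthdata as sd
from tcellcircuits.screens import gene_test, guide_lfc, classify_regulators

effects = {
    "G0000": {"Teff_rest": -2.0, "Teff_stim": -2.0},
    "G0001": {"Teff_rest": 2.0, "Teff_stim": -2.0},
    "G0002": {"Teff_stim": -2.0},
}
cfg = sd.ScreenSimConfig(n_genes=30, guides_per_gene=4, n_control_guides=30,
                         cells_per_guide=500, depth=500_000,
                         conditions=("Teff_rest", "Teff_stim"),
                         donors_per_condition={"Teff_rest": 2, "Teff_stim": 2},
                         effect_map=effects, seed=7)
counts, truth = sd.simulate_screen(cfg)
res = gene_test(guide_lfc(counts), n_perm=5000, seed=0)
print(res["Teff_stim"].table.sort_values("fdr").head(4).round(3))
cls = classify_regulators(res)
print(cls.categories.loc[["G0000", "G0001", "G0002"]].to_dict())
```

```
       median_lfc  p_perm  n_guides    fdr  direction
gene
G0000       8.535   0.001         4  0.009          1
G0001       8.509   0.001         4  0.009          1
G0002       7.940   0.002         4  0.016          1
G0025      -1.003   0.044         4  0.328         -1
{'G0000': 'consistent', 'G0001': 'differential', 'G0002': 'context_specific'}
```

All three planted regulators are significant in the stimulated screen with
large positive median lfc (knockouts accumulate in the phenotype-low bin ⇒
positive regulators), the first background gene sits at FDR 0.33, and the
cross-condition classifier recovers each planted category.  The same flow
is available from the shell:

```bash
tcc simulate screen --seed 7 --out-dir sim
tcc screen test sim/counts.tsv sim/guide_map.tsv sim/samples.tsv --out-dir res
tcc screen classify res/gene_results_*.tsv --out-dir res
```

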
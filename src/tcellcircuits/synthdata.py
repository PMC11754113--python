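"""Synthetic data generators for every analysis stage.

The generators emulate the study designs the analyses assume: a
sort-and-sequence CRISPR screen with FACS bins (top/bottom 20% of cells by
surface phenotype), negative-binomial single-cell and bulk RNA-seq counts
with donor effects, a stimulation-driven activation program with per-target
perturbation effects, and chromatin coverage tracks with controllable
promoter-proximal pausing plus an exogenous spike-in genome fraction
(default 2.5%).  Each generator also returns the ground truth it planted.

A single global seed expands into per-component substreams via
``numpy.random.SeedSequence(seed, spawn_key)`` where the spawn key is derived
from a stable CRC32 of the component name: the same (seed, component) pair
always yields the same stream regardless of call order.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd

from .io_formats import CTRL_GENE, CoverageTrack, GeneModel, SampleSheet
from .screens import ScreenCounts


def rng_for(seed: int, *component: str) -> np.random.Generator:
    """Deterministic named substream of the global seed."""
    key = tuple(zlib.crc32(c.encode()) for c in component)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


@dataclass
class SimTruth:
    """Ground-truth record of every effect a generator planted."""

    kind: str
    payload: dict

    def write_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"kind": self.kind, **self.payload}, fh, indent=2, default=float)
            fh.write("\n")


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean, dispersion) via gamma-Poisson; dispersion 0 degrades to Poisson."""
    mean = np.asarray(mean, float)
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


# ---------------------------------------------------------------------------
# sorted-bin screen
# ---------------------------------------------------------------------------

@dataclass
class ScreenSimConfig:
    """Study conditions for the sorted-screen generator.

    ``effect_map`` maps gene → {condition: β}, a latent-expression shift in
    units of the within-condition cell-to-cell s.d.; cells carrying a guide
    against that gene have their latent phenotype shifted by β, so negative β
    sends knockouts into the low bin (positive regulator convention).
    Defaults mirror the screens' design: 20% sort bins, 4 guides per gene,
    donors 3/3/2 across the Teff-rest, Teff-stim and Treg-rest conditions.
    """

    n_genes: int = 100
    guides_per_gene: int = 4
    n_control_guides: int = 100
    cells_per_guide: int = 500
    effect_map: dict[str, dict[str, float]] = field(default_factory=dict)
    conditions: tuple[str, ...] = ("Teff_rest", "Teff_stim", "Treg_rest")
    donors_per_condition: dict[str, int] = field(
        default_factory=lambda: {"Teff_rest": 3, "Teff_stim": 3, "Treg_rest": 2})
    sort_fraction: float = 0.20
    depth: int = 1_000_000
    dispersion: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.sort_fraction < 0.5:
            raise ValueError("sort_fraction must lie in (0, 0.5)")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")

    @property
    def gene_names(self) -> list[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)]


def simulate_screen(cfg: ScreenSimConfig) -> tuple[ScreenCounts, SimTruth]:
    """Simulate a sort-and-sequence screen at the cell level.

    Per condition/donor, every cell draws a latent phenotype
    x ~ Normal(β_gene, 1); the bottom ``sort_fraction`` of cells forms the
    low bin and the top fraction the high bin.  Per-bin guide compositions
    are then sequenced to ``depth`` reads with NB overdispersion
    (gamma-weighted multinomial).
    """
    genes = cfg.gene_names
    guide_ids, guide_genes = [], []
    for g in genes:
        for j in range(cfg.guides_per_gene):
            guide_ids.append(f"{g}_sg{j}")
            guide_genes.append(g)
    for j in range(cfg.n_control_guides):
        guide_ids.append(f"CTRL_sg{j}")
        guide_genes.append(CTRL_GENE)
    guide_map = pd.Series(guide_genes, index=pd.Index(guide_ids, name="guide"), name="gene")
    n_guides = len(guide_ids)
    beta_by_cond = {
        c: np.array([cfg.effect_map.get(g, {}).get(c, 0.0) for g in guide_genes])
        for c in cfg.conditions
    }

    sheet_rows, count_cols = [], {}
    for cond in cfg.conditions:
        for d in range(cfg.donors_per_condition.get(cond, 2)):
            donor = f"D{d + 1}"
            rng = rng_for(cfg.seed, "screen", cond, donor)
            guide_of_cell = np.repeat(np.arange(n_guides), cfg.cells_per_guide)
            x = rng.normal(beta_by_cond[cond][guide_of_cell], 1.0)
            order = np.argsort(x, kind="stable")
            n_sorted = int(round(cfg.sort_fraction * len(x)))
            low_cells = order[:n_sorted]
            high_cells = order[-n_sorted:]
            for bin_name, cells in (("low", low_cells), ("high", high_cells)):
                comp = np.bincount(guide_of_cell[cells], minlength=n_guides).astype(float)
                if cfg.dispersion > 0:
                    w = comp * rng.gamma(1.0 / cfg.dispersion, cfg.dispersion, size=n_guides)
                else:
                    w = comp
                p = w / w.sum()
                reads = rng.multinomial(cfg.depth, p)
                sid = f"{cond}_{donor}_{bin_name}"
                sheet_rows.append((sid, cond, donor, bin_name))
                count_cols[sid] = reads
    sheet = SampleSheet(pd.DataFrame(sheet_rows,
                                     columns=["sample_id", "condition", "donor", "bin"]))
    counts = pd.DataFrame(count_cols, index=guide_map.index)
    truth = SimTruth("screen", {
        "effect_map": cfg.effect_map,
        "conditions": list(cfg.conditions),
        "sort_fraction": cfg.sort_fraction,
        "genes": genes,
    })
    return ScreenCounts(counts=counts, guide_map=guide_map, sheet=sheet), truth


# ---------------------------------------------------------------------------
# single-cell perturbation matrix
# ---------------------------------------------------------------------------

@dataclass
class PerturbSimConfig:
    """Study conditions for the pooled-perturbation single-cell generator.

    ``program_genes`` maps gene → stimulation log2FC (the activation
    program expressed by stimulated control cells).  ``target_effects`` maps
    perturbation target → {condition: multiplier} applied multiplicatively to
    program-gene expression in cells carrying that perturbation.
    """

    n_genes: int = 100
    n_cells_per_target: int = 150
    donors: int = 2
    baseline_mean: float = 2.0
    program_genes: dict[str, float] = field(default_factory=dict)
    target_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    nt_fraction: float = 0.25
    dispersion: float = 0.3
    cell_type: str = "Teff"
    donor_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.nt_fraction <= 1:
            raise ValueError("nt_fraction must lie in (0, 1]")
        for t, eff in self.target_effects.items():
            if any(m <= 0 for m in eff.values()):
                raise ValueError(f"target {t}: multipliers must be > 0")
        if self.target_effects and not self.program_genes:
            raise ValueError("target_effects need a non-empty activation program")

    @property
    def gene_names(self) -> list[str]:
        return [f"g{i:04d}" for i in range(self.n_genes)]


def simulate_perturb(cfg: PerturbSimConfig) -> tuple[ad.AnnData, SimTruth]:
    """Simulate a perturbation single-cell experiment as an AnnData.

    Counts are NB with per-donor library-size effects; stimulated cells
    express program genes at 2^stim_lfc × baseline; target cells additionally
    multiply program-gene expression by the per-condition target multiplier.
    obs columns: target, donor, condition, cell_type.
    """
    genes = cfg.gene_names
    unknown = set(cfg.program_genes) - set(genes)
    if unknown:
        raise ValueError(f"program genes outside the gene set: {sorted(unknown)[:5]}")
    rng = rng_for(cfg.seed, "perturb")
    baseline = cfg.baseline_mean * rng.lognormal(0.0, 0.5, size=cfg.n_genes)
    stim_lfc = np.array([cfg.program_genes.get(g, 0.0) for g in genes])
    donor_sf = np.exp(rng.normal(0.0, cfg.donor_sd, size=cfg.donors))

    targets = list(cfg.target_effects)
    if cfg.nt_fraction >= 1.0 or not targets:
        plan = [("NT", cfg.n_cells_per_target)]
    else:
        n_targeting = len(targets) * cfg.n_cells_per_target
        n_nt = max(1, int(round(n_targeting * cfg.nt_fraction / (1 - cfg.nt_fraction))))
        plan = [(t, cfg.n_cells_per_target) for t in targets] + [("NT", n_nt)]

    X_rows, obs_rows = [], []
    for condition in ("rest", "stim"):
        act = 1.0 if condition == "stim" else 0.0
        for target, n_cells in plan:
            mult = cfg.target_effects.get(target, {}).get(condition, 1.0)
            gene_mult = np.where(stim_lfc != 0.0, mult, 1.0)
            mu = baseline * 2 ** (stim_lfc * act) * gene_mult
            for c in range(n_cells):
                donor = c % cfg.donors
                X_rows.append(_nb_counts(rng, mu * donor_sf[donor], cfg.dispersion))
                obs_rows.append((target, f"D{donor + 1}", condition, cfg.cell_type))
    X = np.vstack(X_rows).astype(np.int64)
    obs = pd.DataFrame(obs_rows, columns=["target", "donor", "condition", "cell_type"])
    obs.index = [f"cell{i:05d}" for i in range(len(obs))]
    adata = ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=pd.Index(genes, name="gene")))
    truth = SimTruth("perturb", {
        "program_genes": cfg.program_genes,
        "target_effects": cfg.target_effects,
        "baseline_mean": {g: float(m) for g, m in zip(genes, baseline)},
    })
    return adata, truth


# ---------------------------------------------------------------------------
# bulk RNA-seq with knockouts
# ---------------------------------------------------------------------------

@dataclass
class BulkSimConfig:
    """Knockout bulk RNA-seq design: targets × {rest, stim} × donors.

    ``stim_genes`` maps gene → log2FC between stimulated and resting control
    samples; ``ko_effects`` maps knockout target → {gene: log2FC} applied in
    all conditions (pass condition-specific maps via ``ko_effects_stim``).
    Defaults use the study's 3-donor design.
    """

    n_genes: int = 200
    donors: int = 3
    baseline_mean: float = 50.0
    targets: tuple[str, ...] = ("AAVS1",)
    stim_genes: dict[str, float] = field(default_factory=dict)
    ko_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    dispersion: float = 0.05
    donor_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.donors < 2:
            raise ValueError("bulk design needs >= 2 donors for DE with a donor covariate")

    @property
    def gene_names(self) -> list[str]:
        return [f"g{i:04d}" for i in range(self.n_genes)]


def simulate_bulk(cfg: BulkSimConfig) -> tuple[pd.DataFrame, SampleSheet, SimTruth]:
    """Simulate a knockout bulk RNA-seq count table with donor offsets."""
    genes = cfg.gene_names
    rng = rng_for(cfg.seed, "bulk")
    baseline = cfg.baseline_mean * rng.lognormal(0.0, 1.0, size=cfg.n_genes)
    stim_lfc = np.array([cfg.stim_genes.get(g, 0.0) for g in genes])
    donor_sf = np.exp(rng.normal(0.0, cfg.donor_sd, size=cfg.donors))

    cols, sheet_rows = {}, []
    for target in cfg.targets:
        ko = cfg.ko_effects.get(target, {})
        ko_lfc = np.array([ko.get(g, 0.0) for g in genes])
        for condition in ("rest", "stim"):
            cond_label = "Teff_rest" if condition == "rest" else "Teff_stim"
            act = 1.0 if condition == "stim" else 0.0
            for d in range(cfg.donors):
                mu = baseline * 2 ** (stim_lfc * act + ko_lfc) * donor_sf[d]
                sid = f"{target}_{condition}_D{d + 1}"
                cols[sid] = _nb_counts(rng, mu, cfg.dispersion)
                sheet_rows.append((sid, cond_label, f"D{d + 1}", target))
    counts = pd.DataFrame(cols, index=pd.Index(genes, name="gene"))
    sheet = SampleSheet(pd.DataFrame(
        sheet_rows, columns=["sample_id", "condition", "donor", "target"]))
    truth = SimTruth("bulk", {"stim_genes": cfg.stim_genes, "ko_effects": cfg.ko_effects})
    return counts, sheet, truth


# ---------------------------------------------------------------------------
# chromatin coverage with pausing and spike-in
# ---------------------------------------------------------------------------

@dataclass
class CoverageSimConfig:
    """Coverage-track generator on a toy contig with controllable pausing.

    ``target_pi`` maps gene → pausing index realized in expectation (read
    density in the ±200 bp TSS window over density in the +400 bp-offset gene
    body).  ``spike_fraction`` of reads land on a separate spike-in contig,
    mirroring exogenous chromatin spiked at a fixed mass fraction (2.5%
    default).
    """

    models: list[GeneModel] = field(default_factory=list)
    target_pi: dict[str, float] = field(default_factory=dict)
    reads: int = 100_000
    spike_fraction: float = 0.025
    read_length: int = 50
    spike_contig: str = "spike1"
    spike_length: int = 20_000
    tss_halfwidth: int = 200
    body_offset: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.spike_fraction < 1:
            raise ValueError("spike_fraction must lie in [0, 1)")
        if any(pi <= 0 for pi in self.target_pi.values()):
            raise ValueError("target PI values must be > 0")
        for m in self.models:
            span = m.span[1] - m.span[0]
            if span < 2 * self.body_offset:
                raise ValueError(
                    f"{m.gene}: gene span {span} bp too short for the "
                    f"{self.body_offset} bp window offsets")


def _rle_track(per_base: dict[str, np.ndarray]) -> CoverageTrack:
    """Run-length encode per-base coverage arrays into a CoverageTrack."""
    rows = []
    for contig, cov in per_base.items():
        if cov.size == 0:
            continue
        change = np.flatnonzero(np.diff(cov)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [cov.size]])
        for s, e in zip(starts, ends):
            if cov[s] != 0:
                rows.append((contig, int(s), int(e), float(cov[s])))
    df = pd.DataFrame(rows, columns=["contig", "start", "end", "value"]) if rows else pd.DataFrame(
        {"contig": pd.Series(dtype=str), "start": pd.Series(dtype=int),
         "end": pd.Series(dtype=int), "value": pd.Series(dtype=float)})
    return CoverageTrack(df)


def simulate_coverage(
    cfg: CoverageSimConfig,
) -> tuple[CoverageTrack, CoverageTrack, dict[str, dict[str, int]], SimTruth]:
    """Simulate ChIP and input coverage tracks realizing per-gene pausing.

    Primary-genome ChIP reads are split per gene between the TSS window and
    the gene body so the density ratio matches the configured PI in
    expectation; input reads are uniform over the primary contig.  A
    ``spike_fraction`` of each track's reads is placed uniformly on the
    spike-in contig.  Returns (chip, input, per-track spike/primary read
    counts, truth).
    """
    if not cfg.models:
        raise ValueError("coverage simulation needs at least one gene model")
    rng = rng_for(cfg.seed, "coverage")
    contig = cfg.models[0].contig
    contig_len = max(m.span[1] for m in cfg.models) + 2 * cfg.body_offset + 1000

    def place(cov: np.ndarray, n: int, lo: int, hi: int) -> None:
        if n <= 0 or hi <= lo:
            return
        starts = rng.integers(lo, hi, size=n)
        for s in starts:
            cov[s:min(s + cfg.read_length, cov.size)] += 1.0

    counts_out: dict[str, dict[str, int]] = {}
    tracks: dict[str, CoverageTrack] = {}
    for name in ("chip", "input"):
        cov = {contig: np.zeros(contig_len), cfg.spike_contig: np.zeros(cfg.spike_length)}
        n_spike = rng.binomial(cfg.reads, cfg.spike_fraction) if cfg.reads else 0
        n_primary = cfg.reads - n_spike
        place(cov[cfg.spike_contig], n_spike, 0, cfg.spike_length)
        if name == "input":
            place(cov[contig], n_primary, 0, contig_len - cfg.read_length)
        else:
            per_gene = np.full(len(cfg.models), n_primary // max(len(cfg.models), 1))
            per_gene[: n_primary % max(len(cfg.models), 1)] += 1
            for m, n_reads in zip(cfg.models, per_gene):
                pi = cfg.target_pi.get(m.gene, 1.0)
                if m.strand == "+":
                    tss_lo, tss_hi = m.tss - cfg.tss_halfwidth, m.tss + cfg.tss_halfwidth
                    body_lo = m.tss + cfg.body_offset
                    body_hi = m.final_exon_end + cfg.body_offset
                else:
                    tss_lo, tss_hi = m.tss - cfg.tss_halfwidth, m.tss + cfg.tss_halfwidth
                    body_hi = m.tss - cfg.body_offset
                    body_lo = m.final_exon_end - cfg.body_offset
                tss_len = tss_hi - tss_lo
                body_len = body_hi - body_lo
                # PI = (t/tss_len)/(b/body_len)  =>  t/b = PI * tss_len/body_len
                f_tss = pi * tss_len / (pi * tss_len + body_len)
                n_tss = rng.binomial(n_reads, f_tss)
                place(cov[contig], n_tss, max(tss_lo, 0), tss_hi)
                place(cov[contig], n_reads - n_tss, max(body_lo, 0), body_hi)
        counts_out[name] = {
            "primary": int(n_primary),
            "spike": int(n_spike),
        }
        tracks[name] = _rle_track(cov)
    truth = SimTruth("coverage", {
        "target_pi": cfg.target_pi,
        "spike_fraction": cfg.spike_fraction,
        "reads": cfg.reads,
        "contig": contig,
        "spike_contig": cfg.spike_contig,
    })
    return tracks["chip"], tracks["input"], counts_out, truth
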
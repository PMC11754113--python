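"""Chromatin analyses: spike-in scaling, enrichment peak calling against a
knockout background, peak segmentation, differential regions with
nearest-TSS annotation, and the RNA polymerase II pausing index.

The pausing index of a gene is the promoter-proximal read density over the
gene-body density: PI = (TSS coverage / TSS length) / (body coverage / body
length), with the TSS window spanning 200 bp on either side of the TSS and
the gene body running from 400 bp downstream of the TSS to 400 bp past the
final exon (strand-aware).  Genes are filtered to those expressed in
matched RNA-seq (base mean > 10).

Spike-in scaling divides track values by the quotient
(primary ChIP / spike ChIP) / (primary input / spike input): a sample with
relatively more primary-genome ChIP signal than its input predicts is
down-scaled.  The peak caller is a simplified Poisson local-lambda model:
both tracks are depth-matched to a common effective total signal, windows
are scored against the max of local (1/5/10 kb) and genome-wide background
rates, BH-corrected, and significant windows are merged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special
from statsmodels.stats.multitest import multipletests

from .io_formats import CoverageTrack, GeneModel
from .network import DEResult, nb_wald_de

TSS_HALFWIDTH = 200
BODY_OFFSET = 400
MAX_REGION_LEN = 5000


@dataclass
class SpikeInCounts:
    chip_primary: int
    chip_spike: int
    input_primary: int
    input_spike: int


@dataclass
class PeakSet:
    peaks: pd.DataFrame           # contig, start, end, score (-log10 q), q
    window: int
    q_lt: float


@dataclass
class RegionMatrix:
    regions: pd.DataFrame         # contig, start, end (each <= 5,000 bp, disjoint)
    counts: pd.DataFrame          # regions × samples integer counts


@dataclass
class PausingTable:
    table: pd.DataFrame           # per gene: tss_cov, body_cov, tss_len, body_len,
                                  # pi, expressed, flagged


def spikein_factor(c: SpikeInCounts) -> float:
    """Scaling quotient s = (chipP/chipS) / (inputP/inputS); tracks divide by s."""
    for name in ("chip_primary", "chip_spike", "input_primary", "input_spike"):
        if getattr(c, name) <= 0:
            raise ValueError(f"{name} must be > 0 for spike-in scaling")
    return (c.chip_primary / c.chip_spike) / (c.input_primary / c.input_spike)


def scale_track(track: CoverageTrack, c: SpikeInCounts) -> CoverageTrack:
    return track.scale(1.0 / spikein_factor(c))


# ---------------------------------------------------------------------------
# peak calling
# ---------------------------------------------------------------------------

def _poisson_sf(k: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """P(Poisson(lam) >= k), continuous in k via the regularized gamma."""
    k = np.asarray(k, float)
    lam = np.asarray(lam, float)
    out = np.ones_like(k)
    pos = k > 0
    out[pos] = special.gammainc(k[pos], lam[pos])
    return out


def call_peaks_vs_background(
    treatment: CoverageTrack,
    background: CoverageTrack,
    window: int = 200,
    q_lt: float = 0.05,
    effective_reads: float = 200_000,
    local_spans: tuple[int, ...] = (1000, 5000, 10_000),
    contigs: list[str] | None = None,
) -> PeakSet:
    """Poisson sliding-window enrichment of treatment over background.

    Window signal is converted to a read-like count by depth-matching both
    tracks to ``effective_reads`` total (read length cancels out of the
    conversion), so uniform rescaling of both tracks leaves the calls
    unchanged.  Each non-overlapping ``window`` is scored by the Poisson
    upper tail at lambda = max(background count in the window itself, local
    background mean over 1/5/10 kb, genome-wide background rate) — the
    window-level term makes signal present in the background (for example a
    knockout that retains binding) mask the call, which is the
    high-confidence-peak semantics.  BH correction runs across windows and
    adjacent significant windows are merged.
    """
    if background.total_signal() == 0:
        raise ValueError("empty background track")
    if treatment.total_signal() == 0:
        return PeakSet(peaks=pd.DataFrame(columns=["contig", "start", "end", "score", "q"]),
                       window=window, q_lt=q_lt)
    t_scale = effective_reads / treatment.total_signal()
    b_scale = effective_reads / background.total_signal()
    if contigs is None:
        contigs = treatment.contigs

    recs = []
    for contig in contigs:
        span_end = 0
        for tr in (treatment, background):
            d = tr.data[tr.data["contig"] == contig]
            if len(d):
                span_end = max(span_end, int(d["end"].max()))
        if span_end == 0:
            continue
        n_win = int(np.ceil(span_end / window))
        edges = np.arange(n_win + 1) * window

        def window_counts(tr: CoverageTrack, scale: float) -> np.ndarray:
            d = tr.data[tr.data["contig"] == contig]
            out = np.zeros(n_win)
            for s, e, v in d[["start", "end", "value"]].itertuples(index=False):
                w0, w1 = int(s // window), int((e - 1) // window)
                for w in range(w0, w1 + 1):
                    ov = min(e, edges[w + 1]) - max(s, edges[w])
                    out[w] += ov * v
            return out * scale

        t_counts = window_counts(treatment, t_scale)
        b_counts = window_counts(background, b_scale)
        genome_rate = b_counts.sum() / n_win
        lam = np.maximum(b_counts, genome_rate)
        cum = np.concatenate([[0.0], np.cumsum(b_counts)])
        for span in local_spans:
            half = max(int(span // window // 2), 1)
            lo = np.clip(np.arange(n_win) - half, 0, n_win)
            hi = np.clip(np.arange(n_win) + half + 1, 0, n_win)
            local_mean = (cum[hi] - cum[lo]) / np.maximum(hi - lo, 1)
            lam = np.maximum(lam, local_mean)
        recs.append((contig, edges, t_counts, lam))

    if not recs:
        return PeakSet(peaks=pd.DataFrame(columns=["contig", "start", "end", "score", "q"]),
                       window=window, q_lt=q_lt)
    all_p = np.concatenate([_poisson_sf(t, lam) for _, _, t, lam in recs])
    all_q = multipletests(all_p, method="fdr_bh")[1]
    rows = []
    off = 0
    for contig, edges, t_counts, lam in recs:
        n_win = len(t_counts)
        q = all_q[off:off + n_win]
        off += n_win
        sig = np.flatnonzero((q < q_lt) & (t_counts > lam))
        if not len(sig):
            continue
        # merge runs of adjacent significant windows
        breaks = np.flatnonzero(np.diff(sig) > 1)
        run_starts = np.concatenate([[0], breaks + 1])
        run_ends = np.concatenate([breaks, [len(sig) - 1]])
        for a, b in zip(run_starts, run_ends):
            w0, w1 = sig[a], sig[b]
            qmin = float(q[w0:w1 + 1].min())
            rows.append((contig, int(edges[w0]), int(edges[w1 + 1]),
                         float(-np.log10(max(qmin, 1e-300))), qmin))
    peaks = pd.DataFrame(rows, columns=["contig", "start", "end", "score", "q"])
    return PeakSet(peaks=peaks, window=window, q_lt=q_lt)


# ---------------------------------------------------------------------------
# region segmentation and differential regions
# ---------------------------------------------------------------------------

def segment_regions(peak_sets: list[PeakSet] | list[pd.DataFrame],
                    max_len: int = MAX_REGION_LEN) -> pd.DataFrame:
    """Union all peaks, then split each merged interval left-to-right into
    chunks of at most ``max_len`` bp.  Output covers exactly the union."""
    frames = []
    for ps in peak_sets:
        df = ps.peaks if isinstance(ps, PeakSet) else ps
        if len(df):
            frames.append(df[["contig", "start", "end"]])
    if not frames:
        return pd.DataFrame(columns=["contig", "start", "end"])
    allp = pd.concat(frames).sort_values(["contig", "start"]).reset_index(drop=True)
    rows = []
    for contig, grp in allp.groupby("contig", sort=True):
        cur_s, cur_e = None, None
        merged = []
        for s, e in grp[["start", "end"]].itertuples(index=False):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                merged.append((cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append((cur_s, cur_e))
        for s, e in merged:
            pos = s
            while pos < e:
                rows.append((contig, pos, min(pos + max_len, e)))
                pos += max_len
    return pd.DataFrame(rows, columns=["contig", "start", "end"])


def region_matrix(regions: pd.DataFrame, tracks: dict[str, CoverageTrack]) -> RegionMatrix:
    """Integer counts per region × sample (value-weighted overlap, rounded)."""
    cols = {}
    for sample, track in tracks.items():
        cols[sample] = [
            int(round(track.window_sum(r.contig, r.start, r.end)))
            for r in regions.itertuples(index=False)
        ]
    idx = pd.Index([f"{r.contig}:{r.start}-{r.end}" for r in regions.itertuples(index=False)],
                   name="region")
    return RegionMatrix(regions=regions.reset_index(drop=True),
                        counts=pd.DataFrame(cols, index=idx))


def nearest_tss(regions: pd.DataFrame, models: list[GeneModel]) -> pd.DataFrame:
    """Annotate each region with the gene whose TSS is nearest the midpoint.

    Ties (equidistant TSSs) resolve to the lexicographically first gene
    symbol and are flagged.
    """
    tss_by_contig: dict[str, list[tuple[int, str]]] = {}
    for m in models:
        tss_by_contig.setdefault(m.contig, []).append((m.tss, m.gene))
    for v in tss_by_contig.values():
        v.sort(key=lambda t: (t[0], t[1]))
    rows = []
    for r in regions.itertuples(index=False):
        mid = (r.start + r.end) // 2
        cands = tss_by_contig.get(r.contig, [])
        if not cands:
            rows.append((None, np.nan, False))
            continue
        dists = [(abs(t - mid), g) for t, g in cands]
        dmin = min(d for d, _ in dists)
        winners = sorted(g for d, g in dists if d == dmin)
        rows.append((winners[0], dmin, len(winners) > 1))
    ann = pd.DataFrame(rows, columns=["nearest_gene", "tss_distance", "tss_tie"])
    return pd.concat([regions.reset_index(drop=True), ann], axis=1)


def differential_regions(
    rm: RegionMatrix,
    group: pd.Series,
    contrast: tuple[str, str],
    donor: pd.Series | None = None,
    models: list[GeneModel] | None = None,
) -> tuple[DEResult, pd.DataFrame | None]:
    """NB Wald differential test over regions, with nearest-TSS annotation."""
    counts = rm.counts
    if (counts.to_numpy() != np.floor(counts.to_numpy())).any():
        raise ValueError("region counts must be integers")
    de = nb_wald_de(counts, group=group, contrast=contrast, donor=donor)
    ann = nearest_tss(rm.regions, models) if models is not None else None
    return de, ann


# ---------------------------------------------------------------------------
# polymerase pausing
# ---------------------------------------------------------------------------

def pausing_index(
    track: CoverageTrack,
    models: list[GeneModel],
    expressed: set[str] | None = None,
    tss_halfwidth: int = TSS_HALFWIDTH,
    body_offset: int = BODY_OFFSET,
) -> PausingTable:
    """Pausing index per gene from base-pair coverage.

    Plus strand: TSS window [tss−200, tss+200), body [tss+400,
    final_exon_end+400); minus strand mirrored.  Genes with zero body
    coverage or non-positive window lengths are flagged with undefined PI
    (never silently 0); genes outside ``expressed`` are excluded from the
    expressed flag but still reported.
    """
    rows = []
    for m in models:
        if m.strand == "+":
            tss_lo, tss_hi = m.tss - tss_halfwidth, m.tss + tss_halfwidth
            body_lo, body_hi = m.tss + body_offset, m.final_exon_end + body_offset
        else:
            tss_lo, tss_hi = m.tss - tss_halfwidth, m.tss + tss_halfwidth
            body_lo, body_hi = m.final_exon_end - body_offset, m.tss - body_offset
        tss_len = tss_hi - tss_lo
        body_len = body_hi - body_lo
        flagged = body_len <= 0
        if flagged:
            rows.append((m.gene, np.nan, np.nan, tss_len, body_len, np.nan, True))
            continue
        tss_cov = track.window_sum(m.contig, tss_lo, tss_hi)
        body_cov = track.window_sum(m.contig, body_lo, body_hi)
        if body_cov == 0:
            rows.append((m.gene, tss_cov, body_cov, tss_len, body_len, np.nan, True))
            continue
        pi = (tss_cov / tss_len) / (body_cov / body_len)
        rows.append((m.gene, tss_cov, body_cov, tss_len, body_len, pi, False))
    tab = pd.DataFrame(rows, columns=["gene", "tss_cov", "body_cov", "tss_len",
                                      "body_len", "pi", "flagged"]).set_index("gene")
    tab["expressed"] = (
        tab.index.isin(expressed) if expressed is not None else True
    )
    return PausingTable(table=tab)
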
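"""Readers/writers for the external formats consumed by the analysis modules.

All genomic coordinates are 0-based half-open throughout the package (BED and
bedGraph native).  Count tables are strictly integer; normalized matrices are
separate in-memory objects and are never serialized as "counts".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CONDITIONS = ("Teff_rest", "Teff_stim", "Treg_rest", "Treg_stim")
BINS = ("high", "low")
#: guide→gene label reserved for non-targeting / safe-harbour control guides
CTRL_GENE = "CTRL"


class FormatError(ValueError):
    """Malformed external file or sample-sheet contract violation."""


# ---------------------------------------------------------------------------
# sample sheets
# ---------------------------------------------------------------------------

@dataclass
class SampleSheet:
    """Per-sample metadata table.

    ``bin`` must be present for sorted-screen tables (exactly one ``high`` and
    one ``low`` sample per (condition, donor)) and absent otherwise.
    ``target`` holds the knockout/knockdown gene symbol where applicable
    ("AAVS1" or "NT" for controls).
    """

    table: pd.DataFrame

    REQUIRED = ("sample_id", "condition", "donor")

    def __post_init__(self) -> None:
        t = self.table
        for col in self.REQUIRED:
            if col not in t.columns:
                raise FormatError(f"sample sheet missing column {col!r}")
        if t["sample_id"].duplicated().any():
            dup = t.loc[t["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise FormatError(f"duplicate sample_id {dup!r}")
        bad = set(t["condition"]) - set(CONDITIONS)
        if bad:
            raise FormatError(f"unknown condition(s) {sorted(bad)}; expected {CONDITIONS}")
        if self.is_screen:
            bad = set(t["bin"].dropna()) - set(BINS)
            if bad:
                raise FormatError(f"unknown bin value(s) {sorted(bad)}")
            for (cond, donor), grp in t.groupby(["condition", "donor"], observed=True):
                if sorted(grp["bin"]) != ["high", "low"]:
                    raise FormatError(
                        f"screen sheet needs exactly one high and one low sample "
                        f"for ({cond}, {donor})"
                    )

    @property
    def is_screen(self) -> bool:
        return "bin" in self.table.columns and self.table["bin"].notna().any()

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SampleSheet":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# count tables
# ---------------------------------------------------------------------------

def read_counts_table(path: str | Path, sheet: SampleSheet) -> pd.DataFrame:
    """Read a TSV count table (rows = features, columns = samples).

    The first column holds the feature id (sgRNA id or gene symbol); the
    remaining columns must cover every sample in ``sheet``.  Counts must be
    non-negative integers.  Column order of the result follows the sheet.
    """
    raw = pd.read_csv(path, sep="\t")
    feat_col = raw.columns[0]
    if raw[feat_col].duplicated().any():
        dup = raw.loc[raw[feat_col].duplicated(), feat_col].iloc[0]
        raise FormatError(f"duplicate feature id {dup!r} in {path}")
    raw = raw.set_index(feat_col)
    missing = [s for s in sheet.sample_ids if s not in raw.columns]
    if missing:
        raise FormatError(f"count table {path} missing sample column(s) {missing}")
    out = raw[sheet.sample_ids]
    for col in out.columns:
        vals = out[col].to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise FormatError(f"non-numeric counts in column {col!r}")
        frac = vals != np.floor(vals)
        if frac.any():
            row = out.index[int(np.argmax(frac))]
            raise FormatError(
                f"non-integer count {vals[np.argmax(frac)]!r} at row {row!r}, column {col!r}"
            )
        if (vals < 0).any():
            row = out.index[int(np.argmax(vals < 0))]
            raise FormatError(f"negative count at row {row!r}, column {col!r}")
    return out.astype(np.int64)


def write_counts_table(counts: pd.DataFrame, path: str | Path, feature_name: str = "feature") -> None:
    counts.rename_axis(feature_name).to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# coverage tracks (bedGraph)
# ---------------------------------------------------------------------------

@dataclass
class CoverageTrack:
    """Sorted, non-overlapping half-open intervals with non-negative values.

    ``data`` columns: contig, start, end, value.  Zero-value intervals are
    dropped on construction; intervals are sorted by (contig, start).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        d = self.data
        expected = ["contig", "start", "end", "value"]
        if list(d.columns) != expected:
            raise FormatError(f"CoverageTrack columns must be {expected}")
        d = d[d["value"] != 0.0].copy()
        if len(d):
            if (d["end"] <= d["start"]).any():
                bad = d[d["end"] <= d["start"]].iloc[0]
                raise FormatError(
                    f"empty or inverted interval {bad['contig']}:{bad['start']}-{bad['end']}"
                )
            if not np.isfinite(d["value"]).all() or (d["value"] < 0).any():
                raise FormatError("track values must be finite and non-negative")
            d = d.sort_values(["contig", "start"], kind="mergesort").reset_index(drop=True)
            for contig, grp in d.groupby("contig", sort=False):
                starts = grp["start"].to_numpy()
                ends = grp["end"].to_numpy()
                if (starts[1:] < ends[:-1]).any():
                    raise FormatError(f"overlapping intervals on contig {contig}")
        self.data = d.reset_index(drop=True)

    @property
    def contigs(self) -> list[str]:
        return list(dict.fromkeys(self.data["contig"]))

    def total_signal(self, contig: str | None = None) -> float:
        """Sum of value x length, optionally restricted to one contig."""
        d = self.data if contig is None else self.data[self.data["contig"] == contig]
        return float(((d["end"] - d["start"]) * d["value"]).sum())

    def window_sum(self, contig: str, start: int, end: int) -> float:
        """Sum of value x overlap over [start, end) on ``contig``."""
        d = self.data[self.data["contig"] == contig]
        if not len(d):
            return 0.0
        s = d["start"].to_numpy()
        e = d["end"].to_numpy()
        v = d["value"].to_numpy()
        ov = np.minimum(e, end) - np.maximum(s, start)
        ov = np.clip(ov, 0, None)
        return float((ov * v).sum())

    def scale(self, factor: float) -> "CoverageTrack":
        d = self.data.copy()
        d["value"] = d["value"] * factor
        return CoverageTrack(d)


def read_bedgraph(path: str | Path) -> CoverageTrack:
    """Read a 4-column bedGraph into a :class:`CoverageTrack`.

    Records may arrive unsorted; the result is sorted.  Track lines and
    comments are skipped.
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 4:
                raise FormatError(f"{path}:{ln}: expected 4 bedGraph fields")
            rows.append((parts[0], int(parts[1]), int(parts[2]), float(parts[3])))
    df = pd.DataFrame(rows, columns=["contig", "start", "end", "value"]) if rows else pd.DataFrame(
        {"contig": pd.Series(dtype=str), "start": pd.Series(dtype=int),
         "end": pd.Series(dtype=int), "value": pd.Series(dtype=float)})
    return CoverageTrack(df)


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    track.data.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# gene models (BED12)
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """Strand-aware gene structure on 0-based half-open coordinates.

    ``tss`` is the leftmost exon start on the + strand and the rightmost exon
    end on the − strand.  ``final_exon_end`` is the transcription-terminal
    exon boundary (strand-aware: rightmost end on +, leftmost start on −).
    """

    gene: str
    contig: str
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"{self.gene}: strand must be + or -")
        if not self.exons:
            raise FormatError(f"{self.gene}: gene model needs at least one exon")
        exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise FormatError(f"{self.gene}: overlapping exons")
        for s, e in exons:
            if e <= s:
                raise FormatError(f"{self.gene}: empty exon [{s}, {e})")
        self.exons = exons

    @property
    def tss(self) -> int:
        return self.exons[0][0] if self.strand == "+" else self.exons[-1][1]

    @property
    def final_exon_end(self) -> int:
        return self.exons[-1][1] if self.strand == "+" else self.exons[0][0]

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from BED12 (blockStarts/blockSizes define exons)."""
    models = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise FormatError(f"{path}:{ln}: BED12 requires 12 fields, got {len(f)}")
            contig, chrom_start, chrom_end, name = f[0], int(f[1]), int(f[2]), f[3]
            strand = f[5]
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise FormatError(f"{path}:{ln}: blockCount does not match block lists")
            exons = [(chrom_start + s, chrom_start + s + z) for s, z in zip(starts, sizes)]
            if any(e > chrom_end for _, e in exons):
                raise FormatError(f"{path}:{ln}: block extends past chromEnd")
            models.append(GeneModel(gene=name, contig=contig, strand=strand, exons=exons))
    return models


def write_gene_models(models: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in models:
            start, end = m.span
            sizes = ",".join(str(e - s) for s, e in m.exons)
            starts = ",".join(str(s - start) for s, _ in m.exons)
            fh.write("\t".join(map(str, [
                m.contig, start, end, m.gene, 0, m.strand,
                start, end, "0", len(m.exons), sizes, starts,
            ])) + "\n")


# ---------------------------------------------------------------------------
# BED6 intervals (peaks / regions)
# ---------------------------------------------------------------------------

def write_bed6(df: pd.DataFrame, path: str | Path, score_col: str = "score") -> None:
    """Write intervals (columns contig/start/end, optional name/score/strand)."""
    out = pd.DataFrame({
        "contig": df["contig"],
        "start": df["start"],
        "end": df["end"],
        "name": df.get("name", pd.Series(["."] * len(df), index=df.index)),
        "score": df.get(score_col, pd.Series([0] * len(df), index=df.index)),
        "strand": df.get("strand", pd.Series(["."] * len(df), index=df.index)),
    })
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bed6(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["contig", "start", "end", "name", "score", "strand"])
    return df


def write_json_manifest(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
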
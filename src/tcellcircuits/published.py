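"""Loaders for externally published result tables and deposited count data.

The study's per-screen gene-level result tables and deposited count files
are distributed through the journal's supplementary material and GEO; they
are not shipped with this package.  Users who have downloaded them can
point these loaders at a directory (default ``data/external/`` at the
repository root) to reproduce the cross-screen hit counts, the GATA3 guide
statistics and the CAR activation signature size on the real data.

Expected files:

- ``screen_<condition>.tsv``: per-screen gene results with columns
  ``gene``, ``lfc``, ``fdr`` (one file per screen condition).
- ``screen_counts.tsv`` + ``screen_samples.tsv``: deposited sgRNA counts
  and a matching sample sheet for the stimulated-Teff screen.
- ``car_counts.tsv`` + ``car_samples.tsv``: CAR-T bulk RNA-seq counts with
  control resting/stimulated samples.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .screens import GeneScreenResult


def published_dir(root: str | Path = ".") -> Path:
    return Path(root) / "data" / "external"


def load_screen_gene_tables(directory: str | Path) -> dict[str, GeneScreenResult]:
    """Load per-screen gene-level results (gene, lfc, fdr) as GeneScreenResult."""
    directory = Path(directory)
    results: dict[str, GeneScreenResult] = {}
    for path in sorted(directory.glob("screen_*.tsv")):
        cond = path.stem.removeprefix("screen_")
        df = pd.read_csv(path, sep="\t")
        need = {"gene", "lfc", "fdr"}
        if not need <= set(df.columns):
            raise ValueError(f"{path}: expected columns {sorted(need)}")
        tab = pd.DataFrame({
            "median_lfc": df["lfc"].to_numpy(),
            "p_perm": df["fdr"].to_numpy(),
            "fdr": df["fdr"].to_numpy(),
            "n_guides": 0,
        }, index=pd.Index(df["gene"], name="gene"))
        tab["direction"] = (tab["median_lfc"] > 0).astype(int) * 2 - 1
        results[cond] = GeneScreenResult(condition=cond, table=tab)
    return results
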
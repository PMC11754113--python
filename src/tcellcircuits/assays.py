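"""Closed-form assay quantifications: suppression-assay normalization and
knockout MFI fold changes."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class SuppressionWell:
    """One suppression-assay well: proliferating responder events plus bead
    counts used to normalize for collection variability."""

    prolif_count: float
    beads_observed: float
    beads_input: float
    ratio_label: str = ""

    def __post_init__(self) -> None:
        if self.beads_observed <= 0:
            raise ValueError("beads_observed must be > 0")


def absolute_proliferating(w: SuppressionWell) -> float:
    """Bead-normalized absolute proliferating responder count:
    prolif_count x beads_input / beads_observed."""
    return w.prolif_count * w.beads_input / w.beads_observed


def percent_suppression(abs_count: float, responder_only_abs_count: float,
                        literal_formula: bool = False) -> float:
    """Percent suppression relative to the responder-only condition.

    The conventional form (1 − ratio) × 100 is the default and yields the
    0–100% scale.  ``literal_formula=True`` instead evaluates
    (100 − ratio) × 100, a dimensionally inconsistent variant retained only
    for auditability.
    """
    if responder_only_abs_count <= 0:
        raise ValueError("responder-only absolute count must be > 0")
    ratio = abs_count / responder_only_abs_count
    if literal_formula:
        return (100.0 - ratio) * 100.0
    return (1.0 - ratio) * 100.0


def mfi_log2fc(ko_mfi: float, control_mfi: float) -> float:
    """log2 fold change of knockout vs control median fluorescence intensity."""
    if ko_mfi <= 0 or control_mfi <= 0:
        raise ValueError("MFI values must be > 0")
    return float(np.log2(ko_mfi / control_mfi))
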
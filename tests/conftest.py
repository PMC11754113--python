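import numpy as np
import pandas as pd
import pytest

from tcellcircuits.io_formats import GeneModel, SampleSheet
from tcellcircuits import synthdata as sd


@pytest.fixture
def screen_sheet() -> SampleSheet:
    rows = []
    for cond in ("Teff_rest", "Teff_stim"):
        for donor in ("D1", "D2"):
            for b in ("high", "low"):
                rows.append((f"{cond}_{donor}_{b}", cond, donor, b))
    return SampleSheet(pd.DataFrame(rows, columns=["sample_id", "condition", "donor", "bin"]))


@pytest.fixture
def toy_models() -> list[GeneModel]:
    return [
        GeneModel(gene=f"gene{i}", contig="chrT", strand="+",
                  exons=[(10_000 + 6000 * i, 13_000 + 6000 * i)])
        for i in range(6)
    ]


@pytest.fixture
def perturb_adata():
    prog = {f"g{i:04d}": 1.0 for i in range(20)}
    cfg = sd.PerturbSimConfig(
        n_genes=60, n_cells_per_target=120, donors=2, nt_fraction=0.5,
        program_genes=prog,
        target_effects={"MEDX": {"rest": 1.5, "stim": 0.6},
                        "NULLT": {"rest": 1.0, "stim": 1.0}},
        seed=11,
    )
    adata, truth = sd.simulate_perturb(cfg)
    return adata, truth, prog
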
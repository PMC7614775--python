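import numpy as np
import pandas as pd
import pytest

from cysengage import (
    ChannelLayout,
    duplicate_design,
    generate_psm_table,
    generate_truths,
)


@pytest.fixture(scope="session")
def noise_free_experiment():
    """Small noise-free competition experiment with one planted site.

    Planted TE50 = 0.1 uM under k_inact = 0.08 / min, 60 min
    preincubation; 4 doses in duplicate plus duplicate DMSO (TMT 10-plex).
    """
    truths = generate_truths(6, liganded={"JAK1_C817": 0.1}, seed=3)
    design = duplicate_design([0.01, 0.1, 1.0, 10.0], noise_cv=0.0, seed=4)
    psms, ledger = generate_psm_table(truths, design)
    layout = ChannelLayout.from_design(design)
    return {"truths": truths, "design": design, "psms": psms,
            "ledger": ledger, "layout": layout}


@pytest.fixture()
def two_channel_layout():
    """Minimal hand-built layout: 2 DMSO + one duplicate compound condition."""
    return ChannelLayout(
        dmso_channels=("126", "127N"),
        treatment_channels={"cpd@1uM": ("127C", "128N")},
        condition_meta={"cpd@1uM": {"compound": "cpd", "conc_uM": 1.0,
                                    "time_min": 60.0}},
    )


def make_psm(protein="P1", residues="100", intensities=None, *,
             peptide="AAACAAAK", tryptic=True, reverse=False):
    """One-row PSM table for the two-channel layout."""
    row = {
        "protein": protein, "peptide": peptide,
        "modified_residues": residues, "charge": 2,
        "is_tryptic": tryptic, "is_reverse": reverse,
    }
    for ch, val in (intensities or {}).items():
        row[f"intensity_{ch}"] = val
    return pd.DataFrame([row])


@pytest.fixture()
def make_psm_row():
    return make_psm
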
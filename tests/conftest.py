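import numpy as np
import pandas as pd
import pytest

import mitoscreen as ms


@pytest.fixture(scope="session")
def standard_panel() -> ms.SyntheticPanel:
    """The standard benchmark panel: 40 lines, 500 genes, 20+20 planted."""
    return ms.generate_panel(seed=0)


@pytest.fixture(scope="session")
def standard_screen(standard_panel):
    corr = ms.correlate_all(standard_panel.expression, standard_panel.effects)
    sel = ms.select_signature(corr)
    return corr, sel


@pytest.fixture()
def noise_free_flux_run() -> ms.FluxRun:
    return ms.generate_flux_run(
        basal_ocr=100.0, oligo_ocr=40.0, fccp_ocr=180.0, rotaa_ocr=20.0,
        basal_ecar=50.0, monensin_ecar=90.0, noise_sd=0.0, n_wells=4, seed=0,
    )


@pytest.fixture()
def small_ct_table() -> pd.DataFrame:
    # control: target 25 / ref 20; treated: target 24 / ref 20
    return pd.DataFrame(
        {
            "sample": ["s_ctrl", "s_ctrl", "s_trt", "s_trt"],
            "condition": ["control", "control", "treated", "treated"],
            "target": ["GENE", "TBP", "GENE", "TBP"],
            "ct": [25.0, 20.0, 24.0, 20.0],
        }
    )


def midrank_oracle(v) -> np.ndarray:
    """Independent mid-rank computation (count-based, no sorting library)."""
    v = np.asarray(v, dtype=float)
    out = np.empty(v.size)
    for i, vi in enumerate(v):
        out[i] = np.sum(v < vi) + (np.sum(v == vi) + 1) / 2.0
    return out


def spearman_oracle(x, y) -> float:
    """Brute-force Spearman rho: Pearson correlation of mid-ranks."""
    rx, ry = midrank_oracle(x), midrank_oracle(y)
    return float(np.corrcoef(rx, ry)[0, 1])
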
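import numpy as np
import pandas as pd
import pytest

from sirna_sensitizer.synthetic import ScreenSimConfig, generate_screen_dataset


@pytest.fixture
def noiseless_null_screen():
    """53-gene screen with no noise, no plate effects, no sensitizers."""
    cfg = ScreenSimConfig(seed=11, noise_sd=0.0, plate_effect_sd=0.0)
    measurements, truth = generate_screen_dataset(cfg)
    return cfg, measurements, truth


@pytest.fixture
def noiseless_planted_screen():
    """Noiseless screen with one planted sensitizer at interaction factor 0.5."""
    cfg = ScreenSimConfig(
        seed=12,
        noise_sd=0.0,
        plate_effect_sd=0.0,
        drugs={"IM": 0.5},
        sensitizer_genes={"IM": ["G05"]},
    )
    measurements, truth = generate_screen_dataset(cfg)
    return cfg, measurements, truth


@pytest.fixture
def small_plate_table():
    """Hand-built single plate pair: 5 GL2 wells and two genes, two replicates."""
    rows = []
    gl2 = [80.0, 90.0, 100.0, 110.0, 120.0]  # median 100
    for plate, cond, drug, pair in [
        ("P1_vehicle", "vehicle", "", "P1"),
        ("P1_drug", "drug", "IM", "P1"),
    ]:
        for i, v in enumerate(gl2):
            rows.append(dict(plate_id=plate, well=f"A{i + 1:02d}", gene="GL2",
                             sirna_id="GL2", condition=cond, drug=drug,
                             plate_pair=pair, raw_value=v))
    for i, (v_veh, v_drug) in enumerate([(90.0, 40.0), (100.0, 100.0)]):
        gene = f"G{i + 1:02d}"
        for rep in range(2):
            rows.append(dict(plate_id="P1_vehicle", well=f"B{2 * i + rep + 1:02d}",
                             gene=gene, sirna_id="pooled", condition="vehicle",
                             drug="", plate_pair="P1", raw_value=v_veh))
            rows.append(dict(plate_id="P1_drug", well=f"B{2 * i + rep + 1:02d}",
                             gene=gene, sirna_id="pooled", condition="drug",
                             drug="IM", plate_pair="P1", raw_value=v_drug))
    return pd.DataFrame(rows)


def bh_stepup_oracle(p):
    """Independent brute-force BH: q_i = min_{j: p_j >= p_i} (p_(j) * m / rank_j)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
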
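import numpy as np
import pandas as pd
import pytest

import neonicmap as nm
from neonicmap.residue_pipeline import CROPS, SEASONS


@pytest.fixture
def simple_registry():
    """Thiamethoxam-style registry: barley 13, canola 21 g/ha, full treatment."""
    return nm.TreatmentRegistry(
        [
            nm.RegistryEntry(1, "barley", "thiamethoxam", 13.0, 1.0,
                             seed_loading=2.6, seeding_rate=5.0),
            nm.RegistryEntry(2, "canola", "thiamethoxam", 21.0, 1.0,
                             seed_loading=4.2, seeding_rate=5.0),
            nm.RegistryEntry(2, "canola", "clothianidin", 10.0, 0.5),
        ]
    )


@pytest.fixture
def canola_grid():
    """10x10 all-canola grid at 100-m pixels (1 ha each)."""
    return nm.CropGrid(np.full((10, 10), 2, dtype=np.int64), 100.0, 2012)


def make_panel_rows(samples, loqs=None, recoveries=None):
    """Long-format panel rows from {(wetland, qs, season, crop): {ai: measured}}.

    Measured values are raw (pre-recovery-correction); AIs not listed get 0.
    """
    loqs = loqs or nm.LOQ_WATER_REPORTING
    recoveries = recoveries or {a: 1.0 for a in nm.AIS}
    rows = []
    for (wid, qs, season, crop), by_ai in samples.items():
        for ai in nm.AIS:
            rows.append(
                {
                    "wetland_id": wid,
                    "qs_id": qs,
                    "season": season,
                    "crop": crop,
                    "crop_prev": crop,
                    "matrix": "water",
                    "ai": ai,
                    "measured": float(by_ai.get(ai, 0.0)),
                    "loq": loqs[ai],
                    "recovery": recoveries[ai],
                    "units": "ng/L",
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture
def two_wetland_panel():
    """Two canola wetlands in one season: one detect (total 10), one blank."""
    rows = make_panel_rows(
        {
            ("W1", "Q1", "summer2012", "canola"): {"clothianidin": 10.0},
            ("W2", "Q1", "summer2012", "canola"): {},
        }
    )
    return nm.WetlandPanel(rows)


def counts_panel(season, n_detected, n_total, level="wetland", qs_size=1):
    """Panel with exactly n_detected of n_total units detected in one season.

    For quarter-section level, each unit is a parcel of ``qs_size``
    wetlands with one detected wetland in detected parcels.
    """
    samples = {}
    for i in range(n_total):
        qs = f"Q{i:03d}"
        for w in range(qs_size if level == "quarter_section" else 1):
            wid = f"{qs}-W{w}"
            hit = i < n_detected and w == 0
            samples[(wid, qs, season, "canola")] = (
                {"clothianidin": 50.0} if hit else {}
            )
    return nm.WetlandPanel(make_panel_rows(samples))


@pytest.fixture
def default_panel():
    panel, truth = nm.gen_residue_panel(nm.PanelConfig(seed=7))
    return panel, truth


def truth_frame(truth):
    """Model frame built from a generator's uncensored ground truth."""
    frame = truth[truth["sampled"]].copy()
    frame["time"] = frame["season"].map({s: float(i) for i, s in enumerate(SEASONS)})
    frame["baseline"] = 0.0
    return frame


RECOVERY_SPEC = nm.LmmSpec(
    random="nested", include_baseline=False, include_prev_crop=False
)


def additive_cells(effects=None, base=None):
    """Additive (crop, season) cell means: season base + crop shift."""
    base = base or {"spring2012": 1.0, "summer2012": 3.0,
                    "fall2012": 0.5, "spring2013": 2.5}
    effects = effects or {}
    return {
        (c, s): base[s] + effects.get(c, 0.0) for c in CROPS for s in SEASONS
    }
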
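"""Synthetic crop landscapes and censored wetland concentration panels.

The study's raw inputs (proprietary land-cover rasters, confidential
treated-percentage data, field measurements) are not publicly available,
so this module generates stand-ins with known ground truth:

* :func:`gen_landscape` builds a crop grid in which each quarter-section
  block carries a single crop (prairie crops are planted at the
  quarter-section scale), drawn from configurable proportions;
* :func:`gen_residue_panel` builds a repeated-measures wetland panel with
  a lognormal total-concentration model — per-(crop, season) cell means on
  the log scale plus Gaussian quarter-section, wetland and residual
  effects — split across active ingredients by mixing weights, censored at
  per-AI LOQs, and thinned in fall by a wetland-drawdown probability.

Both generators are deterministic under a fixed seed and return their
ground truth so parameter-recovery and round-trip tests can compare
estimates against the simulated truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .residue_pipeline import (
    AIS,
    CROPS,
    LOQ_WATER_REPORTING,
    RECOVERY_WATER,
    SEASONS,
    WetlandPanel,
)
from .treatment_atlas import CropGrid

__all__ = [
    "LandscapeConfig",
    "PanelConfig",
    "gen_landscape",
    "gen_residue_panel",
    "default_cell_means",
    "CROP_CODES",
    "DEFAULT_CROP_PROPORTIONS",
]

#: Integer codes for the simulated crop map (0 = non-cropland).
CROP_CODES = {
    "nodata": 0,
    "barley": 1,
    "canola": 2,
    "oat": 3,
    "pea": 4,
    "wheat": 5,
    "grassland": 6,
}

#: Crop shares of sampled wetlands in the field study (canola-dominated
#: rotation with a grassland/hayfield reference stratum).
DEFAULT_CROP_PROPORTIONS = {
    "canola": 0.40,
    "barley": 0.20,
    "wheat": 0.18,
    "oat": 0.11,
    "grassland": 0.11,
}


@dataclass(frozen=True)
class LandscapeConfig:
    """Configuration of the block-structured crop landscape.

    ``block_px`` pixels per quarter-section edge (8 at 100-m resolution
    approximates the 65-ha parcel); ``proportions`` maps crop names (keys
    of :data:`CROP_CODES`) to block probabilities summing to 1.
    """

    shape: tuple[int, int] = (80, 80)
    resolution_m: float = 100.0
    block_px: int = 8
    year: int = 2012
    proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CROP_PROPORTIONS)
    )
    nodata_code: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.block_px < 1:
            raise InvalidParameterError("block_px must be >= 1")
        if self.block_px > min(self.shape):
            raise InvalidParameterError(
                f"block ({self.block_px} px) larger than grid {self.shape}"
            )
        props = np.array(list(self.proportions.values()), dtype=float)
        if np.any(props < 0) or not np.isclose(props.sum(), 1.0):
            raise InvalidParameterError("proportions must be >= 0 and sum to 1")
        unknown = set(self.proportions) - set(CROP_CODES)
        if unknown:
            raise InvalidParameterError(f"unknown crops in proportions: {sorted(unknown)}")


def gen_landscape(cfg: LandscapeConfig) -> CropGrid:
    """Generate a crop grid with one crop per quarter-section block."""
    rng = np.random.default_rng(cfg.seed)
    nrow, ncol = cfg.shape
    b = cfg.block_px
    n_brow = -(-nrow // b)
    n_bcol = -(-ncol // b)
    names = list(cfg.proportions)
    codes = np.array([CROP_CODES[n] for n in names])
    probs = np.array([cfg.proportions[n] for n in names], dtype=float)
    probs = probs / probs.sum()
    block_codes = rng.choice(codes, size=(n_brow, n_bcol), p=probs)
    grid = np.repeat(np.repeat(block_codes, b, axis=0), b, axis=1)[:nrow, :ncol]
    return CropGrid(grid.astype(np.int64), cfg.resolution_m, cfg.year, cfg.nodata_code)


# ---------------------------------------------------------------------------
# Residue panel
# ---------------------------------------------------------------------------

def default_cell_means() -> dict[tuple[str, str], float]:
    """Default log-scale (crop, season) cell means for the panel generator.

    Emulates the observed seasonal pattern of water totals (ng/L): low
    pre-seeding concentrations, a summer peak after seeding in cropped
    fields, a post-harvest fall decline, and a spring rebound after
    snowmelt; grassland wetlands sit near or below the LOQs throughout.
    Season bases are calibrated against the generator's own censoring
    model (default variances, AI weights, recoveries, LOQs) so the
    marginal wetland detection frequencies approximate the observed
    36 / 62 / 16 / 91 percent across the four seasons.
    """
    season_base = {
        "spring2012": -0.465,
        "summer2012": 0.768,
        "fall2012": -1.603,
        "spring2013": 2.880,
    }
    crop_shift = {
        "grassland": -2.5,
        "barley": 0.2,
        "canola": 0.6,
        "oat": 0.0,
        "pea": -0.8,
        "wheat": -0.2,
    }
    return {
        (crop, season): float(season_base[season] + crop_shift[crop])
        for crop in CROPS
        for season in SEASONS
    }


@dataclass(frozen=True)
class PanelConfig:
    """Configuration of the censored wetland concentration panel.

    Defaults follow the field design: 50 quarter sections with up to
    three replicate wetlands each, four sampling seasons, nested Gaussian
    variance components on the log scale, clothianidin-dominant AI mixing
    weights, the reporting LOQ set, assay mean recoveries, and a fall
    drawdown probability sized to the observed fall sample loss
    (80 of 136 wetlands still sampled).
    """

    n_qs: int = 50
    wetlands_per_qs: int = 3
    seasons: tuple[str, ...] = SEASONS
    crop_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CROP_PROPORTIONS)
    )
    cell_means: dict[tuple[str, str], float] = field(default_factory=default_cell_means)
    var_qs: float = 1.0
    var_wetland: float = 0.8
    var_resid: float = 1.0
    ai_weights: dict[str, float] = field(
        default_factory=lambda: {
            "clothianidin": 0.6,
            "thiamethoxam": 0.3,
            "imidacloprid": 0.07,
            "acetamiprid": 0.03,
        }
    )
    loqs: dict[str, float] = field(default_factory=lambda: dict(LOQ_WATER_REPORTING))
    recoveries: dict[str, float] = field(default_factory=lambda: dict(RECOVERY_WATER))
    fall_drawdown_p: float = 0.41
    matrix: str = "water"
    units: str = "ng/L"
    stratified_crops: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_qs < 1 or not (1 <= self.wetlands_per_qs <= 3):
            raise InvalidParameterError(
                "need n_qs >= 1 and 1 <= wetlands_per_qs <= 3"
            )
        for name in ("var_qs", "var_wetland", "var_resid"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if not (0.0 <= self.fall_drawdown_p <= 1.0):
            raise InvalidParameterError("fall_drawdown_p must lie in [0, 1]")
        props = np.array(list(self.crop_proportions.values()), dtype=float)
        if np.any(props < 0) or not np.isclose(props.sum(), 1.0):
            raise InvalidParameterError("crop proportions must be >= 0 and sum to 1")
        w = np.array(list(self.ai_weights.values()), dtype=float)
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise InvalidParameterError("AI weights must be >= 0 and sum to 1")
        unknown = set(self.ai_weights) - set(AIS)
        if unknown:
            raise InvalidParameterError(f"unknown AIs in weights: {sorted(unknown)}")


def gen_residue_panel(cfg: PanelConfig) -> tuple[WetlandPanel, pd.DataFrame]:
    """Generate a censored wetland panel plus its ground truth.

    Per sample the log total is ``cell_mean(crop, season) + u_qs +
    u_wetland + e`` with independent Gaussian effects; the
    back-transformed total is split across AIs by the mixing weights;
    each AI concentration is reported as an uncorrected measurement
    (truth x recovery) and censored at its LOQ by the pipeline. Fall
    samples are dropped with the drawdown probability.

    Returns ``(panel, truth)`` where ``truth`` has one row per
    (wetland, season) with the uncensored log total and each simulated
    effect.
    """
    rng = np.random.default_rng(cfg.seed)
    crops = list(cfg.crop_proportions)
    crop_p = np.array([cfg.crop_proportions[c] for c in crops], dtype=float)
    crop_p /= crop_p.sum()

    qs_ids = [f"QS{q:03d}" for q in range(cfg.n_qs)]
    if cfg.stratified_crops:
        # deterministic largest-remainder allocation (every stratum with
        # positive proportion is represented when n_qs allows), shuffled
        raw = crop_p * cfg.n_qs
        counts = np.floor(raw).astype(int)
        short = cfg.n_qs - counts.sum()
        for i in np.argsort(-(raw - counts))[:short]:
            counts[i] += 1
        qs_crop = rng.permutation(np.repeat(crops, counts))
        qs_crop_prev = rng.permutation(np.repeat(crops, counts))
    else:
        qs_crop = rng.choice(crops, size=cfg.n_qs, p=crop_p)
        qs_crop_prev = rng.choice(crops, size=cfg.n_qs, p=crop_p)
    u_qs = rng.normal(0.0, np.sqrt(cfg.var_qs), size=cfg.n_qs)

    rows = []
    truth_rows = []
    ais = list(cfg.ai_weights)
    weights = np.array([cfg.ai_weights[a] for a in ais], dtype=float)
    for qi, qs in enumerate(qs_ids):
        for wi in range(cfg.wetlands_per_qs):
            wid = f"{qs}-W{wi}"
            u_w = rng.normal(0.0, np.sqrt(cfg.var_wetland))
            for season in cfg.seasons:
                resid = rng.normal(0.0, np.sqrt(cfg.var_resid))
                dropped = season == "fall2012" and rng.random() < cfg.fall_drawdown_p
                mu = cfg.cell_means[(qs_crop[qi], season)]
                log_total = mu + u_qs[qi] + u_w + resid
                total = float(np.exp(log_total))
                truth_rows.append(
                    {
                        "wetland_id": wid,
                        "qs_id": qs,
                        "season": season,
                        "crop": qs_crop[qi],
                        "crop_prev": qs_crop_prev[qi],
                        "cell_mean": mu,
                        "u_qs": u_qs[qi],
                        "u_wetland": u_w,
                        "resid": resid,
                        "log_total": log_total,
                        "total": total,
                        "sampled": not dropped,
                    }
                )
                if dropped:
                    continue
                for ai, w in zip(ais, weights):
                    true_conc = total * w
                    measured = true_conc * cfg.recoveries[ai]
                    rows.append(
                        {
                            "wetland_id": wid,
                            "qs_id": qs,
                            "season": season,
                            "crop": qs_crop[qi],
                            "crop_prev": qs_crop_prev[qi],
                            "matrix": cfg.matrix,
                            "ai": ai,
                            "measured": measured,
                            "loq": cfg.loqs[ai],
                            "recovery": cfg.recoveries[ai],
                            "units": cfg.units,
                        }
                    )
    panel = WetlandPanel(pd.DataFrame(rows))
    truth = pd.DataFrame(truth_rows)
    return panel, truth
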
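"""Censored wetland-residue measurements -> detection and concentration summaries.

Wetland water (ng/L) and sediment (ug/kg wet weight) samples are analyzed
for four neonicotinoid active ingredients (clothianidin, thiamethoxam,
imidacloprid, acetamiprid). Measurements below the limit of quantification
(LOQ) are censored ("ND"). This module turns a long-format sample table into

* recovery-corrected concentrations,
* per-sample total neonicotinoid concentration (non-censored AIs summed,
  justified by the additive toxicity of shared-receptor compounds),
* detection frequencies at the wetland or quarter-section level, and
* per-(season, crop) summary tables of detection %, arithmetic mean and
  maximum concentration.

Conventions (documented in docs/methods.md): a measurement exactly at the
LOQ counts as detected; censored values contribute zero to sums and
arithmetic means (an over-detects-only mean is available); percentages are
rounded half-up to integers for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    DataFormatError,
    EmptyGroupError,
    InvalidCategoryError,
    InvalidMeasurementError,
    InvalidParameterError,
    InvalidSampleError,
)
from .treatment_atlas import round_half_up

__all__ = [
    "AIS",
    "LOQ_WATER_REPORTING",
    "LOQ_WATER_METHODS",
    "RECOVERY_WATER",
    "RECOVERY_SEDIMENT",
    "SEASONS",
    "CROPS",
    "WetlandPanel",
    "apply_recovery_correction",
    "censor_at_loq",
    "total_neonic_concentration",
    "detection_frequency",
    "crop_season_summary",
    "read_panel_csv",
    "write_panel_csv",
]

#: Active ingredients, in reporting order.
AIS = ("imidacloprid", "thiamethoxam", "clothianidin", "acetamiprid")

#: Water LOQs (ng/L) as used in the summary-table footnotes (default set).
LOQ_WATER_REPORTING = {
    "acetamiprid": 0.25,
    "clothianidin": 0.6,
    "thiamethoxam": 0.9,
    "imidacloprid": 0.55,
}

#: Water LOQs (ng/L) from the analytical-methods description (exactly double).
LOQ_WATER_METHODS = {
    "acetamiprid": 0.5,
    "clothianidin": 1.2,
    "thiamethoxam": 1.8,
    "imidacloprid": 1.1,
}

#: Mean assay recoveries (fractions) for fortified water samples.
RECOVERY_WATER = {
    "thiamethoxam": 0.888,
    "clothianidin": 0.789,
    "imidacloprid": 0.859,
    "acetamiprid": 0.896,
}

#: Mean assay recoveries (fractions) for fortified sediment samples.
RECOVERY_SEDIMENT = {
    "thiamethoxam": 0.736,
    "clothianidin": 0.723,
    "imidacloprid": 0.735,
    "acetamiprid": 0.745,
}

#: Sampling seasons in chronological order.
SEASONS = ("spring2012", "summer2012", "fall2012", "spring2013")

#: Surrounding-field crop strata, grassland/hayfield as the reference.
CROPS = ("grassland", "barley", "canola", "oat", "pea", "wheat")

_PANEL_COLUMNS = [
    "wetland_id",
    "qs_id",
    "season",
    "crop",
    "crop_prev",
    "matrix",
    "ai",
    "measured",
    "loq",
    "recovery",
    "units",
]


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def apply_recovery_correction(measured: float, recovery_fraction: float) -> float:
    """Correct a measured concentration for incomplete assay recovery.

    corrected = measured / recovery_fraction, with recovery in (0, 1].
    """
    if not (0.0 < recovery_fraction <= 1.0):
        raise InvalidParameterError(
            f"recovery fraction must lie in (0, 1], got {recovery_fraction}"
        )
    if not (np.isfinite(measured) and measured >= 0):
        raise InvalidMeasurementError(f"measured must be finite and >= 0, got {measured}")
    return float(measured) / float(recovery_fraction)


def censor_at_loq(measured: float, loq: float) -> tuple[float, bool]:
    """Censor a measurement at the limit of quantification.

    Returns ``(value, censored)`` where the value is 0 when censored
    (censored results contribute zero to sums and means downstream). A
    measurement exactly at the LOQ counts as detected.
    """
    if not (np.isfinite(loq) and loq > 0):
        raise InvalidParameterError(f"LOQ must be positive, got {loq}")
    if not (np.isfinite(measured) and measured >= 0):
        raise InvalidMeasurementError(f"measured must be >= 0, got {measured}")
    censored = measured < loq
    return (0.0 if censored else float(measured), bool(censored))


# ---------------------------------------------------------------------------
# Panel container
# ---------------------------------------------------------------------------

@dataclass
class WetlandPanel:
    """Long-format collection of censored residue measurements.

    One row per (wetland, season, matrix, AI) with columns
    ``wetland_id, qs_id, season, crop, crop_prev, matrix, ai, measured,
    loq, recovery, units``. ``measured`` is the raw (pre-correction)
    concentration. Wetlands missing in a season (dry or flooded) simply
    have no rows for that season and drop out of its denominator.
    """

    data: pd.DataFrame
    seasons: tuple[str, ...] = SEASONS
    crops: tuple[str, ...] = CROPS
    _derived: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        missing = set(_PANEL_COLUMNS) - set(self.data.columns)
        if missing:
            raise DataFormatError(f"panel table missing columns {sorted(missing)}")
        df = self.data
        if (df["measured"] < 0).any():
            raise InvalidMeasurementError("negative measured concentration in panel")
        if (df["loq"] <= 0).any():
            raise InvalidParameterError("all LOQs must be positive")
        if ((df["recovery"] <= 0) | (df["recovery"] > 1)).any():
            raise InvalidParameterError("recoveries must lie in (0, 1]")
        bad_crop = set(df["crop"].unique()) - set(self.crops)
        if bad_crop:
            raise InvalidCategoryError(f"unknown crop labels {sorted(bad_crop)}")
        dup = df.duplicated(subset=["wetland_id", "season", "matrix", "ai"])
        if dup.any():
            raise InvalidSampleError(
                "duplicate (wetland, season, matrix, ai) rows in panel"
            )
        mixed = df.groupby(["wetland_id", "season", "matrix"])["units"].nunique()
        if (mixed > 1).any():
            raise InvalidSampleError("mixed units within one sample")

    def matrices(self) -> list[str]:
        return sorted(self.data["matrix"].unique())

    @property
    def samples(self) -> pd.DataFrame:
        """Per-sample table with recovery-corrected, censored totals.

        One row per (wetland, season, matrix): metadata plus per-AI
        corrected values (0 when censored) and the total neonicotinoid
        concentration.
        """
        if self._derived is None:
            df = self.data.copy()
            # censoring is decided on the raw measurement; detects are then
            # recovery-corrected (correction cannot turn an ND into a detect)
            censored = df["measured"] < df["loq"]
            df["value"] = np.where(censored, 0.0, df["measured"] / df["recovery"])
            df["censored"] = censored
            wide = df.pivot_table(
                index=["wetland_id", "qs_id", "season", "crop", "crop_prev", "matrix"],
                columns="ai",
                values="value",
                aggfunc="first",
                fill_value=0.0,
            ).reset_index()
            wide.columns.name = None
            ai_cols = [c for c in wide.columns if c in set(df["ai"].unique())]
            wide["total"] = wide[ai_cols].sum(axis=1)
            wide["detected"] = wide[ai_cols].gt(0).any(axis=1)
            self._derived = wide
        return self._derived


def total_neonic_concentration(sample: pd.DataFrame) -> float:
    """Total neonicotinoid concentration of one sample.

    ``sample`` holds the long-format AI rows of a single (wetland, season,
    matrix) sample. Censored AIs contribute zero; detects are recovery-
    corrected and summed.
    """
    if sample["matrix"].nunique() > 1 or sample["units"].nunique() > 1:
        raise InvalidSampleError("sample mixes matrices or units")
    total = 0.0
    for _, row in sample.iterrows():
        value, censored = censor_at_loq(row["measured"], row["loq"])
        if not censored:
            total += apply_recovery_correction(value, row["recovery"])
    return total


# ---------------------------------------------------------------------------
# Panel-level summaries
# ---------------------------------------------------------------------------

def detection_frequency(
    panel: WetlandPanel,
    season: str,
    level: str = "wetland",
    matrix: str | None = None,
) -> tuple[int, int, int]:
    """Detection frequency for one season at wetland or quarter-section level.

    A wetland counts as detected when at least one AI is at or above its
    LOQ (after recovery correction); a quarter section counts when any of
    its sampled wetlands is detected. Returns ``(numerator, denominator,
    percent)`` with the percentage rounded half-up to an integer.
    """
    if level not in {"wetland", "quarter_section"}:
        raise InvalidParameterError(f"unknown level {level!r}")
    samples = panel.samples
    sub = samples[samples["season"] == season]
    if matrix is not None:
        sub = sub[sub["matrix"] == matrix]
    if sub.empty:
        raise EmptyGroupError(f"no samples for season {season!r}")
    if level == "wetland":
        num = int(sub["detected"].sum())
        den = int(len(sub))
    else:
        by_qs = sub.groupby("qs_id")["detected"].any()
        num = int(by_qs.sum())
        den = int(len(by_qs))
    pct = int(round_half_up(100.0 * num / den))
    return num, den, pct


def crop_season_summary(
    panel: WetlandPanel,
    matrix: str,
    mean_over: str = "all",
) -> pd.DataFrame:
    """Per-(season, crop) detection and concentration summary.

    For every season, crop stratum (grassland included as reference) and
    analyte (each AI and the total), reports the number of sampled
    wetlands, detection percentage, arithmetic mean and maximum of the
    recovery-corrected censored concentrations.

    ``mean_over="all"`` (default) averages over all sampled wetlands with
    censored values as zero; ``mean_over="detects"`` averages the detects
    only (the printed-table denominator convention is not recoverable, so
    both are provided).
    """
    if mean_over not in {"all", "detects"}:
        raise InvalidParameterError(f"unknown mean_over {mean_over!r}")
    samples = panel.samples
    sub = samples[samples["matrix"] == matrix]
    if sub.empty:
        raise EmptyGroupError(f"no samples for matrix {matrix!r}")
    ai_cols = [a for a in AIS if a in sub.columns]
    analytes = ["total"] + ai_cols
    rows = []
    for season in [s for s in panel.seasons if s in set(sub["season"])]:
        s_df = sub[sub["season"] == season]
        crops = [c for c in panel.crops if c in set(s_df["crop"])]
        for crop in crops + ["__overall__"]:
            grp = s_df if crop == "__overall__" else s_df[s_df["crop"] == crop]
            n = len(grp)
            det_pct = int(round_half_up(100.0 * grp["detected"].sum() / n))
            rec: dict[str, object] = {
                "season": season,
                "crop": "overall" if crop == "__overall__" else crop,
                "n": n,
                "detection_pct": det_pct,
            }
            for col in analytes:
                vals = grp[col]
                detects = vals[vals > 0]
                if mean_over == "all":
                    mean = float(vals.mean())
                else:
                    mean = float(detects.mean()) if len(detects) else 0.0
                rec[f"{col}_mean"] = mean
                rec[f"{col}_max"] = float(vals.max()) if n else 0.0
            rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_panel_csv(path: str | Path) -> WetlandPanel:
    """Read a long-format sample table (one AI measurement per row)."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise DataFormatError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = set(_PANEL_COLUMNS) - set(df.columns)
    if missing:
        raise DataFormatError(f"{path}: missing columns {sorted(missing)}")
    crops = tuple(dict.fromkeys(list(CROPS) + sorted(df["crop"].unique())))
    seasons = tuple(dict.fromkeys(list(SEASONS) + sorted(df["season"].unique())))
    return WetlandPanel(df, seasons=seasons, crops=crops)


def write_panel_csv(panel: WetlandPanel, path: str | Path) -> None:
    panel.data[_PANEL_COLUMNS].to_csv(path, index=False)
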
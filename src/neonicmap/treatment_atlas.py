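"""Estimated seed-treatment use rasters from a crop grid and a treatment registry.

Seed-treatment insecticide use is not directly reported on the Canadian
Prairies, so per-hectare use is estimated by combining three ingredients:

* a gridded crop-classification map (integer crop codes per pixel),
* label application rates per crop and active ingredient (AI), expressed as
  seed loading (g AI/kg seed) times seeding rate (kg seed/ha), and
* the fraction of each crop's planted area sown with treated seed.

Every pixel of a given crop receives the *expected* application rate
``resolved_rate x treated_fraction`` (g AI/ha); per-AI rasters are summed
into a total-use raster; pixels are aggregated to quarter-section parcels
(the 65-ha land-survey unit on which prairie crops are planted); parcel
rates are binned into rate categories and rolled up into treated area,
percent of cropland, and total AI mass.

The treated fraction is applied deterministically as an expected-value
multiplier rather than by stochastic pixel selection, so all outputs are
reproducible and aggregate to the same treated areas.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    DataFormatError,
    IncompatibleRasterError,
    InvalidParameterError,
    OutOfRangeError,
)

__all__ = [
    "CropGrid",
    "TreatmentRegistry",
    "RegistryEntry",
    "UseRaster",
    "RateCategory",
    "UseSummary",
    "DEFAULT_RATE_CATEGORIES",
    "application_rate",
    "pixel_area_ha",
    "build_use_raster",
    "merge_use_rasters",
    "aggregate_quarter_sections",
    "categorize_rates",
    "summarize_use",
    "read_crop_grid",
    "write_crop_grid",
    "write_use_raster",
    "read_registry_csv",
    "write_registry_csv",
    "read_categories_csv",
    "round_half_up",
    "sigfig",
]

HA_M2 = 10_000.0  # square metres per hectare


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CropGrid:
    """Integer-coded crop raster on a metric grid.

    Parameters
    ----------
    codes
        2-D integer array of crop codes.
    resolution_m
        Pixel edge length in metres (e.g. 56 or 30 for the source land-cover
        products, 100 for a 1-ha pixel).
    year
        Calendar year of the classification.
    nodata_code
        Code marking non-cropland pixels; must not collide with registry
        crop codes.
    """

    codes: np.ndarray
    resolution_m: float
    year: int
    nodata_code: int = 0

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes)
        if codes.ndim != 2 or codes.size == 0:
            raise InvalidParameterError("crop grid must be a non-empty 2-D array")
        if not np.issubdtype(codes.dtype, np.integer):
            raise InvalidParameterError("crop codes must be integers")
        if not (np.isfinite(self.resolution_m) and self.resolution_m > 0):
            raise InvalidParameterError(
                f"resolution_m must be positive, got {self.resolution_m}"
            )
        object.__setattr__(self, "codes", codes)

    @property
    def shape(self) -> tuple[int, int]:
        return self.codes.shape

    @property
    def pixel_area_ha(self) -> float:
        return pixel_area_ha(self.resolution_m)


@dataclass(frozen=True)
class RegistryEntry:
    """One (crop, active ingredient) row of the treatment registry.

    ``resolved_rate`` is seed loading (g AI/kg seed) x seeding rate
    (kg seed/ha) when both are given, otherwise supplied directly; crops
    with several label rates are reduced to their median before entry.
    """

    crop_code: int
    crop_name: str
    ai: str
    resolved_rate: float  # g AI/ha
    treated_fraction: float
    seed_loading: float | None = None  # g AI / kg seed
    seeding_rate: float | None = None  # kg seed / ha

    def __post_init__(self) -> None:
        if self.seed_loading is not None and self.seeding_rate is not None:
            expected = application_rate(self.seed_loading, self.seeding_rate)
            if not np.isclose(expected, self.resolved_rate, rtol=1e-9, atol=1e-12):
                raise InvalidParameterError(
                    f"resolved_rate {self.resolved_rate} inconsistent with "
                    f"seed_loading x seeding_rate = {expected} "
                    f"for ({self.crop_name}, {self.ai})"
                )
        if not (np.isfinite(self.resolved_rate) and self.resolved_rate >= 0):
            raise InvalidParameterError("resolved_rate must be finite and >= 0")
        if not (0.0 <= self.treated_fraction <= 1.0):
            raise InvalidParameterError(
                f"treated_fraction must lie in [0, 1], got {self.treated_fraction}"
            )


@dataclass
class TreatmentRegistry:
    """Per-(crop, AI) application rates and treated fractions."""

    entries: list[RegistryEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[int, str]] = set()
        for e in self.entries:
            key = (e.crop_code, e.ai)
            if key in seen:
                raise InvalidParameterError(
                    f"duplicate registry entry for crop {e.crop_code}, AI {e.ai!r}"
                )
            seen.add(key)

    @property
    def ais(self) -> list[str]:
        out: list[str] = []
        for e in self.entries:
            if e.ai not in out:
                out.append(e.ai)
        return out

    @property
    def crop_codes(self) -> set[int]:
        return {e.crop_code for e in self.entries}

    def lookup(self, crop_code: int, ai: str) -> RegistryEntry | None:
        for e in self.entries:
            if e.crop_code == crop_code and e.ai == ai:
                return e
        return None


@dataclass(frozen=True)
class UseRaster:
    """Per-pixel expected application rate in g AI/ha.

    ``rates`` already folds in the treated fraction (expected-value
    convention), so summing ``rates x pixel area`` yields expected mass.
    ``treated_fraction_grid`` carries the per-pixel treated fraction for
    area accounting.
    """

    rates: np.ndarray
    treated_fraction_grid: np.ndarray
    resolution_m: float
    year: int
    ai_label: str

    def __post_init__(self) -> None:
        rates = np.asarray(self.rates, dtype=float)
        frac = np.asarray(self.treated_fraction_grid, dtype=float)
        if rates.shape != frac.shape:
            raise InvalidParameterError("rates and fraction grid shapes differ")
        if np.any(rates < 0) or not np.all(np.isfinite(rates)):
            raise InvalidParameterError("rates must be finite and >= 0")
        if np.any((frac < 0) | (frac > 1)):
            raise InvalidParameterError("treated fractions must lie in [0, 1]")
        object.__setattr__(self, "rates", rates)
        object.__setattr__(self, "treated_fraction_grid", frac)

    @property
    def shape(self) -> tuple[int, int]:
        return self.rates.shape

    @property
    def pixel_area_ha(self) -> float:
        return pixel_area_ha(self.resolution_m)


@dataclass(frozen=True)
class RateCategory:
    """Half-open application-rate bin (lower, upper], g AI/ha."""

    name: str
    lower: float  # exclusive
    upper: float  # inclusive

    def __post_init__(self) -> None:
        if not self.upper > self.lower:
            raise InvalidParameterError(
                f"category {self.name!r}: upper bound must exceed lower bound"
            )

    def contains(self, rate: float) -> bool:
        return self.lower < rate <= self.upper


#: The five rate categories used for prairie-wide reporting (g AI/ha).
DEFAULT_RATE_CATEGORIES: tuple[RateCategory, ...] = (
    RateCategory("Low", 0.0, 1.25),
    RateCategory("Low-Medium", 1.25, 4.0),
    RateCategory("Medium", 4.0, 10.5),
    RateCategory("Medium-High", 10.5, 26.0),
    RateCategory("High", 26.0, 70.0),
)


@dataclass(frozen=True)
class UseSummary:
    """Treated-area / mass roll-up of a use raster.

    Areas in hectares, mass in kilograms of active ingredient; percentages
    unrounded (use :func:`round_half_up` / :func:`sigfig` for reporting).
    """

    category_area_ha: dict[str, float]
    category_pct: dict[str, float]
    total_treated_area_ha: float
    total_mass_kg: float
    percent_of_cropland: float
    total_cropland_ha: float


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def application_rate(seed_loading: float, seeding_rate: float) -> float:
    """Application rate (g AI/ha) = seed loading (g AI/kg) x seeding rate (kg/ha)."""
    for name, v in (("seed_loading", seed_loading), ("seeding_rate", seeding_rate)):
        if not (np.isfinite(v) and v >= 0):
            raise InvalidParameterError(f"{name} must be finite and >= 0, got {v}")
    return float(seed_loading) * float(seeding_rate)


def pixel_area_ha(resolution_m: float) -> float:
    """Hectares per pixel for a square pixel of edge ``resolution_m`` metres."""
    if not (np.isfinite(resolution_m) and resolution_m > 0):
        raise InvalidParameterError(
            f"resolution_m must be positive and finite, got {resolution_m}"
        )
    return float(resolution_m) ** 2 / HA_M2


def build_use_raster(grid: CropGrid, registry: TreatmentRegistry, ai: str) -> UseRaster:
    """Expected per-pixel use of one active ingredient.

    Each pixel of crop ``c`` gets rate ``resolved_rate(c, ai) x
    treated_fraction(c, ai)``; crops without a registry entry for ``ai``
    (and nodata pixels) carry rate 0 and fraction 0.
    """
    if not registry.entries:
        raise InvalidParameterError("registry is empty")
    if ai not in registry.ais:
        raise InvalidParameterError(f"AI {ai!r} not present in registry")
    if grid.nodata_code in registry.crop_codes:
        raise ConfigurationError(
            f"nodata code {grid.nodata_code} collides with a registry crop code"
        )
    rates = np.zeros(grid.shape, dtype=float)
    fracs = np.zeros(grid.shape, dtype=float)
    for e in registry.entries:
        if e.ai != ai:
            continue
        mask = grid.codes == e.crop_code
        rates[mask] = e.resolved_rate * e.treated_fraction
        fracs[mask] = e.treated_fraction
    return UseRaster(rates, fracs, grid.resolution_m, grid.year, ai)


def merge_use_rasters(rasters: list[UseRaster]) -> UseRaster:
    """Sum per-AI rasters into a total-use raster for one year.

    Rates add pixel-wise; the merged treated fraction is the per-pixel
    maximum of the component fractions (a pixel is treated if treated by
    any AI, and per-crop fractions refer to the same planted area).
    """
    if not rasters:
        raise InvalidParameterError("no rasters to merge")
    first = rasters[0]
    for r in rasters[1:]:
        if r.shape != first.shape:
            raise IncompatibleRasterError(
                f"shape mismatch: {r.shape} vs {first.shape}"
            )
        if r.resolution_m != first.resolution_m:
            raise IncompatibleRasterError(
                f"resolution mismatch: {r.resolution_m} vs {first.resolution_m}"
            )
        if r.year != first.year:
            raise IncompatibleRasterError(f"year mismatch: {r.year} vs {first.year}")
    rates = np.sum([r.rates for r in rasters], axis=0)
    fracs = np.max([r.treated_fraction_grid for r in rasters], axis=0)
    return UseRaster(rates, fracs, first.resolution_m, first.year, "total")


def aggregate_quarter_sections(
    raster: UseRaster, qs_target_ha: float = 65.0
) -> pd.DataFrame:
    """Tile a use raster into quarter-section-like parcels.

    The raster is cut into axis-aligned square blocks whose pixel count
    best approximates ``qs_target_ha`` (65 ha, the prairie land-survey
    planting unit); at 100-m pixels that is an 8x8 block (64 ha). Edge
    blocks are truncated and area-weighted.

    Returns a DataFrame with columns ``row``, ``col`` (block indices),
    ``mean_rate`` (area-weighted mean expected rate, g AI/ha), ``area_ha``
    (true parcel area) and ``treated_area_ha`` (fraction-weighted area).
    """
    if not (np.isfinite(qs_target_ha) and qs_target_ha > 0):
        raise InvalidParameterError("qs_target_ha must be positive")
    px_ha = raster.pixel_area_ha
    if qs_target_ha < px_ha:
        raise InvalidParameterError(
            f"parcel size {qs_target_ha} ha is smaller than one pixel ({px_ha} ha)"
        )
    block = max(1, int(round(np.sqrt(qs_target_ha / px_ha))))
    nrow, ncol = raster.shape
    records = []
    for bi, r0 in enumerate(range(0, nrow, block)):
        for bj, c0 in enumerate(range(0, ncol, block)):
            tile = raster.rates[r0 : r0 + block, c0 : c0 + block]
            ftile = raster.treated_fraction_grid[r0 : r0 + block, c0 : c0 + block]
            n_px = tile.size
            records.append(
                {
                    "row": bi,
                    "col": bj,
                    "mean_rate": float(tile.mean()),
                    "area_ha": n_px * px_ha,
                    # treated area counts fractions only on pixels with a
                    # positive expected rate, matching the raster roll-up
                    "treated_area_ha": float(ftile[tile > 0].sum()) * px_ha,
                }
            )
    return pd.DataFrame.from_records(records)


def categorize_rates(
    parcels: pd.DataFrame,
    categories: tuple[RateCategory, ...] = DEFAULT_RATE_CATEGORIES,
) -> pd.DataFrame:
    """Bin treated parcels into rate categories by area.

    Parcels with mean rate 0 are untreated and excluded. Bins are
    half-open (lower, upper], upper-inclusive, so a boundary rate such as
    4 g/ha falls in the bin whose upper edge it equals. Percentages are
    of total treated area. A rate above the top bin raises
    :class:`OutOfRangeError`.
    """
    if np.any(parcels["area_ha"] <= 0):
        raise InvalidParameterError("parcel areas must be positive")
    cats = sorted(categories, key=lambda c: c.lower)
    areas = {c.name: 0.0 for c in cats}
    top = cats[-1].upper
    for rate, area in zip(parcels["mean_rate"], parcels["area_ha"]):
        if rate <= 0:
            continue
        if rate > top:
            raise OutOfRangeError(
                f"rate {rate} g/ha exceeds top category bound {top} g/ha"
            )
        for c in cats:
            if c.contains(rate):
                areas[c.name] += float(area)
                break
    total = sum(areas.values())
    pct = {k: (100.0 * v / total if total > 0 else 0.0) for k, v in areas.items()}
    return pd.DataFrame(
        {
            "category": list(areas),
            "lower_g_ha": [c.lower for c in cats],
            "upper_g_ha": [c.upper for c in cats],
            "area_ha": list(areas.values()),
            "pct_within": [pct[c.name] for c in cats],
        }
    )


def summarize_use(
    raster: UseRaster,
    categories: tuple[RateCategory, ...] = DEFAULT_RATE_CATEGORIES,
    total_cropland_ha: float | None = None,
    qs_target_ha: float = 65.0,
) -> UseSummary:
    """Roll a use raster up into treated area, category areas and AI mass.

    Treated area is the fraction-weighted pixel area over pixels with a
    positive expected rate; mass (kg) is the expected rate times pixel
    area summed and divided by 1000. Category areas come from
    quarter-section parcel means. ``total_cropland_ha`` defaults to the
    raster's own cropland area (pixels with positive treated fraction);
    pass the external cropland estimate for prairie-wide percentages.
    """
    px_ha = raster.pixel_area_ha
    treated_mask = raster.rates > 0
    treated_area = float(raster.treated_fraction_grid[treated_mask].sum()) * px_ha
    mass_kg = float((raster.rates * px_ha).sum()) / 1000.0
    if total_cropland_ha is None:
        total_cropland_ha = treated_area
    if total_cropland_ha <= 0:
        raise InvalidParameterError("total_cropland_ha must be positive")
    parcels = aggregate_quarter_sections(raster, qs_target_ha)
    # category areas use fraction-weighted (treated) parcel area so the
    # per-category areas sum to the total treated area
    binnable = parcels[parcels["treated_area_ha"] > 0][
        ["mean_rate", "treated_area_ha"]
    ].rename(columns={"treated_area_ha": "area_ha"})
    cat_df = categorize_rates(binnable, categories)
    category_area = dict(zip(cat_df["category"], cat_df["area_ha"]))
    category_pct = dict(zip(cat_df["category"], cat_df["pct_within"]))
    pct_cropland = 100.0 * treated_area / total_cropland_ha
    return UseSummary(
        category_area_ha=category_area,
        category_pct=category_pct,
        total_treated_area_ha=treated_area,
        total_mass_kg=mass_kg,
        percent_of_cropland=pct_cropland,
        total_cropland_ha=float(total_cropland_ha),
    )


# ---------------------------------------------------------------------------
# Reporting helpers
# ---------------------------------------------------------------------------

def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (the convention of printed percentages)."""
    factor = 10.0 ** ndigits
    return float(np.floor(np.abs(x) * factor + 0.5) / factor * np.sign(x)) if x else 0.0


def sigfig(x: float, n: int = 3) -> float:
    """Round to ``n`` significant figures (areas in Mha are reported at 3)."""
    if x == 0 or not np.isfinite(x):
        return float(x)
    exponent = int(np.floor(np.log10(abs(x))))
    return round_half_up(x, ndigits=n - 1 - exponent)


# ---------------------------------------------------------------------------
# I/O: grids as single-band TIFF or plain-text matrices, tables as CSV
# ---------------------------------------------------------------------------

_REGISTRY_COLUMNS = [
    "crop_code",
    "crop_name",
    "ai",
    "seed_loading_g_per_kg",
    "seeding_rate_kg_per_ha",
    "resolved_rate_g_per_ha",
    "treated_fraction",
]


def read_crop_grid(
    path: str | Path, resolution_m: float, year: int, nodata_code: int = 0
) -> CropGrid:
    """Read a crop grid from a single-band TIFF (.tif) or whitespace matrix."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        try:
            arr = tifffile.imread(path)
        except Exception as exc:  # pragma: no cover - corrupt file path
            raise DataFormatError(f"{path}: cannot read TIFF ({exc})") from exc
        if arr.ndim != 2:
            raise DataFormatError(f"{path}: expected single-band raster, got band shape {arr.shape}")
        codes = arr.astype(np.int64)
    else:
        try:
            codes = np.loadtxt(path, dtype=np.int64, ndmin=2)
        except Exception as exc:
            raise DataFormatError(f"{path}: cannot parse text matrix ({exc})") from exc
    return CropGrid(codes, resolution_m, year, nodata_code)


def write_crop_grid(grid: CropGrid, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        tifffile.imwrite(path, grid.codes.astype(np.int32))
    else:
        np.savetxt(path, grid.codes, fmt="%d")


def write_use_raster(raster: UseRaster, path: str | Path) -> None:
    """Write the expected-rate grid as float TIFF or text matrix."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        tifffile.imwrite(path, raster.rates.astype(np.float32))
    else:
        np.savetxt(path, raster.rates, fmt="%.6g")


def read_registry_csv(path: str | Path) -> TreatmentRegistry:
    """Read the treatment registry.

    Columns: ``crop_code,crop_name,ai,seed_loading_g_per_kg,
    seeding_rate_kg_per_ha,resolved_rate_g_per_ha,treated_fraction``.
    ``resolved_rate_g_per_ha`` may be blank when loading and seeding rate
    are both given.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise DataFormatError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = set(_REGISTRY_COLUMNS[:3]) | {"treated_fraction"}
    missing -= set(df.columns)
    if missing:
        raise DataFormatError(f"{path}: missing columns {sorted(missing)}")
    entries = []
    for i, row in df.iterrows():
        loading = row.get("seed_loading_g_per_kg")
        seeding = row.get("seeding_rate_kg_per_ha")
        resolved = row.get("resolved_rate_g_per_ha")
        loading = None if pd.isna(loading) else float(loading)
        seeding = None if pd.isna(seeding) else float(seeding)
        if pd.isna(resolved):
            if loading is None or seeding is None:
                raise DataFormatError(
                    f"{path}: line {i + 2}: need either resolved rate or "
                    "both seed loading and seeding rate"
                )
            resolved = application_rate(loading, seeding)
        entries.append(
            RegistryEntry(
                crop_code=int(row["crop_code"]),
                crop_name=str(row["crop_name"]),
                ai=str(row["ai"]),
                resolved_rate=float(resolved),
                treated_fraction=float(row["treated_fraction"]),
                seed_loading=loading,
                seeding_rate=seeding,
            )
        )
    return TreatmentRegistry(entries)


def write_registry_csv(registry: TreatmentRegistry, path: str | Path) -> None:
    rows = [
        {
            "crop_code": e.crop_code,
            "crop_name": e.crop_name,
            "ai": e.ai,
            "seed_loading_g_per_kg": e.seed_loading,
            "seeding_rate_kg_per_ha": e.seeding_rate,
            "resolved_rate_g_per_ha": e.resolved_rate,
            "treated_fraction": e.treated_fraction,
        }
        for e in registry.entries
    ]
    pd.DataFrame(rows, columns=_REGISTRY_COLUMNS).to_csv(path, index=False)


def read_categories_csv(path: str | Path) -> tuple[RateCategory, ...]:
    """Read rate categories: columns ``name,lower_g_ha,upper_g_ha``."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise DataFormatError(f"{path}: cannot parse CSV ({exc})") from exc
    needed = {"name", "lower_g_ha", "upper_g_ha"} - set(df.columns)
    if needed:
        raise DataFormatError(f"{path}: missing columns {sorted(needed)}")
    return tuple(
        RateCategory(str(r["name"]), float(r["lower_g_ha"]), float(r["upper_g_ha"]))
        for _, r in df.iterrows()
    )
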
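"""Treatment-atlas unit and property tests.

The brute-force oracle used throughout enumerates pixels one at a time,
independent of the vectorized implementation path.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import neonicmap as nm
from neonicmap.errors import (
    IncompatibleRasterError,
    InvalidParameterError,
    OutOfRangeError,
)
from neonicmap.treatment_atlas import DEFAULT_RATE_CATEGORIES


# --- elementary rate arithmetic -------------------------------------------

@pytest.mark.parametrize(
    "loading,seeding,expected",
    [(0.0, 5.0, 0.0), (4.2, 5.0, 21.0), (2.6, 5.0, 13.0)],
)
def test_application_rate(loading, seeding, expected):
    assert nm.application_rate(loading, seeding) == pytest.approx(expected)


@pytest.mark.parametrize("bad", [(-1.0, 5.0), (1.0, float("nan")), (1.0, float("inf"))])
def test_application_rate_rejects_bad_input(bad):
    with pytest.raises(InvalidParameterError):
        nm.application_rate(*bad)


@pytest.mark.parametrize("res,expected", [(100, 1.0), (56, 0.3136), (30, 0.09)])
def test_pixel_area_ha(res, expected):
    assert nm.pixel_area_ha(res) == pytest.approx(expected)


def test_pixel_area_rejects_nonpositive():
    with pytest.raises(InvalidParameterError):
        nm.pixel_area_ha(0)


# --- raster construction ---------------------------------------------------

def test_uniform_canola_field(canola_grid, simple_registry):
    r = nm.build_use_raster(canola_grid, simple_registry, "thiamethoxam")
    assert np.allclose(r.rates, 21.0)
    assert np.allclose(r.treated_fraction_grid, 1.0)


def test_partial_treatment_is_expected_value(canola_grid, simple_registry):
    r = nm.build_use_raster(canola_grid, simple_registry, "clothianidin")
    assert np.allclose(r.rates, 5.0)  # 10 g/ha x fraction 0.5
    assert np.allclose(r.treated_fraction_grid, 0.5)


def test_nodata_grid_gives_zero_raster(simple_registry):
    grid = nm.CropGrid(np.zeros((4, 4), dtype=np.int64), 100.0, 2012)
    r = nm.build_use_raster(grid, simple_registry, "thiamethoxam")
    assert np.all(r.rates == 0) and np.all(r.treated_fraction_grid == 0)


def test_unknown_ai_and_empty_registry_rejected(canola_grid, simple_registry):
    with pytest.raises(InvalidParameterError):
        nm.build_use_raster(canola_grid, simple_registry, "acetamiprid")
    with pytest.raises(InvalidParameterError):
        nm.build_use_raster(canola_grid, nm.TreatmentRegistry([]), "thiamethoxam")


def test_merge_identity_sum_and_commutativity(canola_grid, simple_registry):
    r = nm.build_use_raster(canola_grid, simple_registry, "thiamethoxam")
    zero = nm.UseRaster(np.zeros(r.shape), np.zeros(r.shape), 100.0, 2012, "none")
    merged = nm.merge_use_rasters([r, zero])
    assert np.allclose(merged.rates, r.rates)
    r2 = nm.build_use_raster(canola_grid, simple_registry, "clothianidin")
    a = nm.merge_use_rasters([r, r2, zero])
    b = nm.merge_use_rasters([zero, r2, r])
    assert np.allclose(a.rates, b.rates) and np.allclose(
        a.treated_fraction_grid, b.treated_fraction_grid
    )
    assert np.allclose(a.rates, 26.0)  # 21 + 5
    assert a.ai_label == "total"


def test_merge_rejects_mismatch(canola_grid, simple_registry):
    r = nm.build_use_raster(canola_grid, simple_registry, "thiamethoxam")
    other = nm.UseRaster(np.zeros((3, 3)), np.zeros((3, 3)), 100.0, 2012, "x")
    with pytest.raises(IncompatibleRasterError):
        nm.merge_use_rasters([r, other])
    wrong_year = nm.UseRaster(np.zeros(r.shape), np.zeros(r.shape), 100.0, 2011, "x")
    with pytest.raises(IncompatibleRasterError):
        nm.merge_use_rasters([r, wrong_year])


# --- quarter-section aggregation -------------------------------------------

def test_uniform_parcels(canola_grid, simple_registry):
    r = nm.build_use_raster(canola_grid, simple_registry, "thiamethoxam")
    parcels = nm.aggregate_quarter_sections(r)
    assert np.allclose(parcels["mean_rate"], 21.0)


def test_truncated_edge_parcels(canola_grid, simple_registry):
    # 10x10 at 100 m with 8x8 blocks -> areas 64, 16, 16, 4 ha
    r = nm.build_use_raster(canola_grid, simple_registry, "thiamethoxam")
    parcels = nm.aggregate_quarter_sections(r, qs_target_ha=65.0)
    assert sorted(parcels["area_ha"]) == [4.0, 16.0, 16.0, 64.0]


def test_half_treated_parcel_mean():
    rates = np.zeros((8, 8))
    rates[:4, :] = 20.0
    fr = (rates > 0).astype(float)
    r = nm.UseRaster(rates, fr, 100.0, 2012, "total")
    parcels = nm.aggregate_quarter_sections(r)
    assert parcels["mean_rate"].iloc[0] == pytest.approx(10.0)


def test_parcel_smaller_than_pixel_rejected(canola_grid, simple_registry):
    r = nm.build_use_raster(canola_grid, simple_registry, "thiamethoxam")
    with pytest.raises(InvalidParameterError):
        nm.aggregate_quarter_sections(r, qs_target_ha=0.5)


# --- rate categories --------------------------------------------------------

@pytest.mark.parametrize(
    "rate,expected",
    [(21.0, "Medium-High"), (4.0, "Low-Medium"), (0.5, "Low"), (70.0, "High")],
)
def test_categorize_boundaries(rate, expected):
    parcels = pd.DataFrame({"mean_rate": [rate], "area_ha": [65.0]})
    out = nm.categorize_rates(parcels)
    assigned = out[out["area_ha"] > 0]["category"].tolist()
    assert assigned == [expected]


def test_rate_zero_excluded_and_above_top_rejected():
    parcels = pd.DataFrame({"mean_rate": [0.0], "area_ha": [65.0]})
    out = nm.categorize_rates(parcels)
    assert out["area_ha"].sum() == 0
    bad = pd.DataFrame({"mean_rate": [71.0], "area_ha": [65.0]})
    with pytest.raises(OutOfRangeError):
        nm.categorize_rates(bad)


def test_default_categories_partition_without_gaps():
    cats = sorted(DEFAULT_RATE_CATEGORIES, key=lambda c: c.lower)
    assert cats[0].lower == 0.0 and cats[-1].upper == 70.0
    for lo, hi in zip(cats, cats[1:]):
        assert lo.upper == hi.lower


@given(st.floats(min_value=1e-6, max_value=70.0, allow_nan=False))
@settings(max_examples=100, deadline=None)
def test_every_positive_rate_lands_in_exactly_one_bin(rate):
    hits = [c for c in DEFAULT_RATE_CATEGORIES if c.contains(rate)]
    assert len(hits) == 1


# --- use summary ------------------------------------------------------------

def test_summary_uniform_field(canola_grid, simple_registry):
    r = nm.build_use_raster(canola_grid, simple_registry, "thiamethoxam")
    s = nm.summarize_use(r)
    assert s.total_treated_area_ha == pytest.approx(100.0)
    assert s.total_mass_kg == pytest.approx(2.1)  # 21 g/ha x 100 ha
    assert s.percent_of_cropland == pytest.approx(100.0)


def test_summary_rejects_bad_cropland(canola_grid, simple_registry):
    r = nm.build_use_raster(canola_grid, simple_registry, "thiamethoxam")
    with pytest.raises(InvalidParameterError):
        nm.summarize_use(r, total_cropland_ha=-1.0)


def test_mass_linearity_and_fraction_monotonicity(canola_grid):
    def registry(rate, frac):
        return nm.TreatmentRegistry(
            [nm.RegistryEntry(2, "canola", "thiamethoxam", rate, frac)]
        )

    base = nm.summarize_use(
        nm.build_use_raster(canola_grid, registry(21.0, 0.5), "thiamethoxam")
    )
    doubled = nm.summarize_use(
        nm.build_use_raster(canola_grid, registry(42.0, 0.5), "thiamethoxam")
    )
    assert doubled.total_mass_kg == pytest.approx(2 * base.total_mass_kg)
    assert doubled.total_treated_area_ha == pytest.approx(base.total_treated_area_ha)

    more_treated = nm.summarize_use(
        nm.build_use_raster(canola_grid, registry(21.0, 0.8), "thiamethoxam")
    )
    assert more_treated.total_treated_area_ha >= base.total_treated_area_ha
    assert more_treated.total_mass_kg >= base.total_mass_kg


# --- brute-force oracle equivalence ----------------------------------------

def brute_force_summary(grid, registry, ais, cropland_ha):
    """Per-pixel enumeration oracle for treated area and mass."""
    px = grid.resolution_m**2 / 10_000.0
    area = 0.0
    mass_g = 0.0
    for i in range(grid.shape[0]):
        for j in range(grid.shape[1]):
            code = int(grid.codes[i, j])
            rate = 0.0
            frac = 0.0
            for ai in ais:
                e = registry.lookup(code, ai)
                if e is not None:
                    rate += e.resolved_rate * e.treated_fraction
                    frac = max(frac, e.treated_fraction)
            if rate > 0:
                area += frac * px
                mass_g += rate * px
    return area, mass_g / 1000.0, 100.0 * area / cropland_ha


@given(st.data())
@settings(max_examples=25, deadline=None)
def test_oracle_equivalence_on_small_grids(data):
    nrow = data.draw(st.integers(2, 20), label="nrow")
    ncol = data.draw(st.integers(2, 20), label="ncol")
    codes = data.draw(
        st.lists(
            st.integers(0, 3), min_size=nrow * ncol, max_size=nrow * ncol
        ),
        label="codes",
    )
    grid = nm.CropGrid(
        np.array(codes, dtype=np.int64).reshape(nrow, ncol), 100.0, 2012
    )
    entries = []
    for code in (1, 2, 3):
        for ai in ("thiamethoxam", "clothianidin"):
            rate = data.draw(st.floats(0.1, 30.0), label=f"rate{code}{ai}")
            frac = data.draw(st.floats(0.05, 1.0), label=f"frac{code}{ai}")
            entries.append(nm.RegistryEntry(code, f"crop{code}", ai, rate, frac))
    registry = nm.TreatmentRegistry(entries)
    rasters = [
        nm.build_use_raster(grid, registry, ai)
        for ai in ("thiamethoxam", "clothianidin")
    ]
    total = nm.merge_use_rasters(rasters)
    summary = nm.summarize_use(total, total_cropland_ha=1000.0)
    area, mass, pct = brute_force_summary(
        grid, registry, ("thiamethoxam", "clothianidin"), 1000.0
    )
    assert summary.total_treated_area_ha == pytest.approx(area, rel=1e-12, abs=1e-12)
    assert summary.total_mass_kg == pytest.approx(mass, rel=1e-12, abs=1e-12)
    assert summary.percent_of_cropland == pytest.approx(pct, rel=1e-12, abs=1e-12)
    # area conservation across categories
    assert sum(summary.category_area_ha.values()) == pytest.approx(
        summary.total_treated_area_ha, rel=1e-6
    )


# --- reporting and I/O -------------------------------------------------------

def test_round_half_up_and_sigfig():
    assert nm.round_half_up(43.97) == 44.0
    assert nm.round_half_up(75.5) == 76.0
    assert nm.round_half_up(-2.5) == -3.0
    assert nm.sigfig(10.993, 3) == 11.0
    assert nm.sigfig(0.013456, 2) == 0.013


def test_grid_and_registry_roundtrip(tmp_path, canola_grid, simple_registry):
    for name in ("grid.txt", "grid.tif"):
        p = tmp_path / name
        nm.write_crop_grid(canola_grid, p)
        back = nm.read_crop_grid(p, 100.0, 2012)
        assert np.array_equal(back.codes, canola_grid.codes)
    reg_path = tmp_path / "registry.csv"
    nm.write_registry_csv(simple_registry, reg_path)
    back = nm.read_registry_csv(reg_path)
    assert len(back.entries) == len(simple_registry.entries)
    e = back.lookup(2, "thiamethoxam")
    assert e.resolved_rate == pytest.approx(21.0)
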
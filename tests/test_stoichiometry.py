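"""Unit and property tests for the rim-allocation model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from incisure.errors import InvalidInputError
from incisure.stoichiometry import (
    DiscGeometry,
    MolarRatioTable,
    RatioEstimate,
    RimModel,
    RodCensus,
    calibrate_rim_density,
    combine_ratios,
    diameter_from_circumference,
    disc_surface_area,
    predict_rim,
    propagate_uncertainty,
    rhodopsin_per_disc_reference,
    round_molecules,
    scale_rhodopsin_by_area,
    tetraspanin_partition,
    tetraspanin_per_disc,
    total_rim_length_from_geometry,
)

positive = st.floats(min_value=1e-3, max_value=1e6, allow_nan=False)


# ---------------------------------------------------------------------------
# Operation examples


@pytest.mark.parametrize(
    "d, expected",
    [(1.5, 3.534), (3.36 / math.pi, 1.797), (1e-6, 2 * math.pi * 2.5e-13)],
)
def test_disc_surface_area(d, expected):
    assert disc_surface_area(d) == pytest.approx(expected, rel=1e-3)


@pytest.mark.parametrize(
    "C, expected", [(3.36, 1.0695), (math.pi, 1.0), (4.712, 1.5)]
)
def test_diameter_from_circumference(C, expected):
    assert diameter_from_circumference(C) == pytest.approx(expected, rel=1e-3)


@pytest.mark.parametrize(
    "rods, discs, expected",
    [(6.0e7, 800, 75_000), (800, 800, 1), (1.2e8, 800, 150_000)],
)
def test_rhodopsin_per_disc(rods, discs, expected):
    census = RodCensus(rods, discs)
    assert rhodopsin_per_disc_reference(census) == pytest.approx(expected)


@pytest.mark.parametrize(
    "ref, a0, a1, expected",
    [(75_000, 3.53, 1.80, 38_244), (75_000, 3.53, 3.53, 75_000),
     (75_000, 3.53, 7.06, 150_000)],
)
def test_scale_rhodopsin_by_area(ref, a0, a1, expected):
    assert scale_rhodopsin_by_area(ref, a0, a1) == pytest.approx(
        expected, rel=1e-3
    )


@pytest.mark.parametrize(
    "rho, ratio, expected",
    [(75_000, 12.7, 5906), (38_200, 6.0, 6367), (100, 1.0, 100)],
)
def test_tetraspanin_per_disc(rho, ratio, expected):
    assert tetraspanin_per_disc(rho, ratio) == pytest.approx(expected, abs=0.5)


@pytest.mark.parametrize(
    "a, b, expected, rel",
    [
        (18.2, 42.2, 12.72, 1e-3),
        (30.9, 29.9, 15.20, 1e-3),
        (7.0, math.inf, 7.0, 1e-9),
    ],
)
def test_combine_ratios(a, b, expected, rel):
    assert combine_ratios(a, b) == pytest.approx(expected, rel=rel)


@pytest.mark.parametrize(
    "a, b, expected",
    [(18.2, 42.2, 2.32), (30.9, 29.9, 0.97), (5.0, 5.0, 1.0)],
)
def test_tetraspanin_partition(a, b, expected):
    assert tetraspanin_partition(a, b) == pytest.approx(expected, abs=0.005)


@pytest.mark.parametrize(
    "d, f, expected",
    [(1.5, 0.50, 6.212), (1.5, 0.0, 4.712), (3.36 / math.pi, 1.55, 6.675)],
)
def test_total_rim_length(d, f, expected):
    assert total_rim_length_from_geometry(d, f) == pytest.approx(
        expected, rel=1e-3
    )


@pytest.mark.parametrize(
    "tet, L, expected",
    [(5906, 6.21, 951.0), (950, 1.0, 950.0), (5910, 6.21, 951.7)],
)
def test_calibrate_rim_density(tet, L, expected):
    assert calibrate_rim_density(tet, L).rim_linear_density == pytest.approx(
        expected, abs=0.5
    )


def test_predict_rim_hemizygote_chain():
    """Budget of ~6360 tetraspanins at WT rim density yields a ~1.66 um
    incisure, ~155% of the disc diameter."""
    geom = DiscGeometry.from_circumference(3.36)
    model = RimModel(rim_linear_density=950.0)
    pred = predict_rim(6360, model, geom)
    assert pred.total_rim_length == pytest.approx(6.695, rel=2e-3)
    assert pred.incisure_length == pytest.approx(1.667, rel=2e-3)
    assert pred.incisure_fraction == pytest.approx(1.559, rel=2e-3)
    assert not pred.enclosure_deficit


def test_predict_rim_exact_enclosure():
    geom = DiscGeometry.from_diameter(1.5)
    model = RimModel(rim_linear_density=950.0)
    pred = predict_rim(950.0 * geom.circumference, model, geom)
    assert pred.incisure_length == pytest.approx(0.0, abs=1e-9)
    assert not pred.enclosure_deficit


def test_predict_rim_deficit_regime():
    """A tetraspanin budget below lambda*C cannot enclose the disc."""
    geom = DiscGeometry.from_diameter(1.5)
    model = RimModel(rim_linear_density=950.0)
    pred = predict_rim(2000, model, geom)
    assert pred.enclosure_deficit
    assert pred.incisure_length == 0.0
    assert pred.total_rim_length == pytest.approx(2.105, abs=2e-3)
    assert pred.deficit_magnitude == pytest.approx(2.607, abs=2e-3)


@pytest.mark.parametrize(
    "func, args",
    [
        (disc_surface_area, (0,)),
        (disc_surface_area, (-1.5,)),
        (diameter_from_circumference, (0,)),
        (scale_rhodopsin_by_area, (75_000, 0, 1.8)),
        (tetraspanin_per_disc, (75_000, -1)),
        (combine_ratios, (0, 42.2)),
        (tetraspanin_partition, (18.2, 0)),
        (total_rim_length_from_geometry, (1.5, -0.1)),
        (calibrate_rim_density, (0, 6.21)),
    ],
)
def test_invalid_inputs_rejected(func, args):
    with pytest.raises(InvalidInputError):
        func(*args)


def test_rod_census_validation():
    with pytest.raises(InvalidInputError):
        RodCensus(6.0e7, 0)


def test_round_molecules_display():
    assert round_molecules(5906.3) == 5910
    assert round_molecules(6367.2) == 6370


# ---------------------------------------------------------------------------
# Properties


@given(a=positive, b=positive)
def test_combine_ratios_harmonic_and_symmetric(a, b):
    c = combine_ratios(a, b)
    assert c == pytest.approx(a * b / (a + b), rel=1e-12)
    assert c == pytest.approx(combine_ratios(b, a), rel=1e-12)
    assert c < min(a, b)


@given(
    a=st.floats(0.1, 1e3),
    b=st.floats(0.1, 1e3),
    delta=st.floats(0.01, 100),
)
def test_combine_ratios_monotone(a, b, delta):
    assert combine_ratios(a + delta, b) > combine_ratios(a, b)


@given(
    d=st.floats(0.2, 10.0),
    f=st.floats(0.0, 2.0),
    tet=st.floats(100.0, 1e6),
)
@settings(max_examples=200)
def test_round_trip_calibration(d, f, tet):
    """Calibrating on (T, d, f) and predicting with the same budget and
    geometry recovers the incisure fraction."""
    L = total_rim_length_from_geometry(d, f)
    model = calibrate_rim_density(tet, L)
    pred = predict_rim(tet, model, DiscGeometry.from_diameter(d))
    assert pred.incisure_fraction == pytest.approx(f, rel=1e-9, abs=1e-12)


@given(tet=st.floats(100.0, 1e6))
def test_rim_accounting_identity(tet):
    geom = DiscGeometry.from_diameter(1.5)
    pred = predict_rim(tet, RimModel(rim_linear_density=950.0), geom)
    if not pred.enclosure_deficit:
        residual = (
            pred.total_rim_length
            - 2 * pred.incisure_length
            - math.pi * geom.diameter
        )
        assert abs(residual) <= 1e-9 * pred.total_rim_length


def test_fraction_decreases_with_ratio_and_boundary_is_continuous(
    ratio_table, census, geometries
):
    """At fixed diameter and rim density, more rhodopsin per tetraspanin
    means a shorter incisure; the deficit boundary is approached with
    L_inc -> 0."""
    geom = geometries["Rho+/-"]
    model = RimModel(rim_linear_density=950.0)
    rho = 38_200
    ratios = np.linspace(2.0, 25.0, 120)
    fracs = [
        predict_rim(tetraspanin_per_disc(rho, r), model, geom).incisure_fraction
        for r in ratios
    ]
    assert all(x >= y for x, y in zip(fracs, fracs[1:]))
    # continuity at the boundary: the exact-enclosure budget gives L_inc = 0
    boundary_ratio = rho / (model.rim_linear_density * geom.circumference)
    for eps in (1e-6, -1e-6):
        pred = predict_rim(
            tetraspanin_per_disc(rho, boundary_ratio * (1 + eps)), model, geom
        )
        assert pred.incisure_length <= 1e-4


# ---------------------------------------------------------------------------
# Ratio table


def test_ratio_table_consistency_enforced():
    with pytest.raises(InvalidInputError):
        MolarRatioTable(
            {
                "X": {
                    "rho_to_prph2": RatioEstimate(18.2),
                    "rho_to_rom1": RatioEstimate(42.2),
                    "rho_to_tetraspanin": RatioEstimate(20.0),
                }
            }
        )


def test_ratio_table_csv_round_trip(tmp_path, ratio_table):
    path = tmp_path / "ratios.csv"
    ratio_table.to_csv(path)
    again = MolarRatioTable.from_csv(path)
    assert set(again.genotypes) == set(ratio_table.genotypes)
    assert again.ratio("WT", "rho_to_tetraspanin").mean == 12.7
    assert again.ratio("rds/+", "rho_to_prph2").sd == 6.0


def test_ratio_table_derives_combined_ratio():
    table = MolarRatioTable(
        {
            "X": {
                "rho_to_prph2": RatioEstimate(18.2),
                "rho_to_rom1": RatioEstimate(42.2),
            }
        }
    )
    assert table.ratio("X", "rho_to_tetraspanin").mean == pytest.approx(
        12.72, abs=0.005
    )


# ---------------------------------------------------------------------------
# Monte-Carlo propagation


def test_propagation_zero_sd_collapses(census, geometries):
    table = MolarRatioTable(
        {
            "WT": {"rho_to_tetraspanin": RatioEstimate(12.7, 0.0, 3)},
            "Rho+/-": {"rho_to_tetraspanin": RatioEstimate(6.0, 0.0, 3)},
        }
    )
    s = propagate_uncertainty(
        table, census, geometries, "incisure_fraction", "Rho+/-",
        n_draws=500, seed=3,
    )
    assert s.ci_low == s.ci_high == pytest.approx(s.point_estimate)


def test_propagation_deterministic_and_straddles_point(
    ratio_table, census, geometries
):
    kwargs = dict(
        quantity="incisure_fraction", genotype="Rho+/-", n_draws=4000, seed=9
    )
    s1 = propagate_uncertainty(ratio_table, census, geometries, **kwargs)
    s2 = propagate_uncertainty(ratio_table, census, geometries, **kwargs)
    assert (s1.ci_low, s1.ci_high) == (s2.ci_low, s2.ci_high)
    assert s1.ci_low <= s1.point_estimate <= s1.ci_high
    assert s1.point_estimate == pytest.approx(1.55, abs=0.02)


def test_propagation_seeds_agree_within_mc_error(ratio_table, census, geometries):
    """Two seeds give CI endpoints within a few Monte-Carlo standard errors."""
    draws = 20_000
    a = propagate_uncertainty(
        ratio_table, census, geometries, "incisure_fraction", "Rho+/-",
        n_draws=draws, seed=1,
    )
    b = propagate_uncertainty(
        ratio_table, census, geometries, "incisure_fraction", "Rho+/-",
        n_draws=draws, seed=2,
    )
    width = a.ci_high - a.ci_low
    # percentile-endpoint MC error is O(width / sqrt(draws)); allow 3x
    tol = 3 * width / math.sqrt(draws) * 10
    assert a.ci_low == pytest.approx(b.ci_low, abs=tol)
    assert a.ci_high == pytest.approx(b.ci_high, abs=tol)


def test_propagation_single_draw_reproducible(ratio_table, census, geometries):
    s1 = propagate_uncertainty(
        ratio_table, census, geometries, "incisure_length", "Rho+/-",
        n_draws=1, seed=42,
    )
    s2 = propagate_uncertainty(
        ratio_table, census, geometries, "incisure_length", "Rho+/-",
        n_draws=1, seed=42,
    )
    assert s1 == s2


def test_propagation_unknown_quantity(ratio_table, census, geometries):
    with pytest.raises(InvalidInputError):
        propagate_uncertainty(
            ratio_table, census, geometries, "nonsense", "Rho+/-", n_draws=10,
            seed=0,
        )
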
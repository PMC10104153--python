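"""Disc rim-allocation model.

A rod outer segment disc is a flattened membrane sac: two lamellar faces
joined by a highly curved rim. Rhodopsin fills the lamellae at a constant
areal packing density, so the rhodopsin count per disc fixes the disc
surface area. The tetraspanins peripherin-2 and ROM1 build the rim, so the
tetraspanin count per disc fixes the total rim length. The rim comprises
the disc circumference plus the incisure -- a deep indentation lined by two
apposed rim edges, so one incisure of length ``L_inc`` consumes
``2 * L_inc`` of rim material:

    L_rim = pi * d + 2 * L_inc

The model is calibrated on the wild type: the measured total rim length and
the tetraspanin budget give a rim linear density ``lambda`` (molecules per
micrometer of rim), assumed genotype-invariant. For any other genotype the
tetraspanin budget divided by ``lambda`` predicts total rim length; material
beyond the circumference is allocated to the incisure, and a budget short of
the circumference is flagged as an *enclosure deficit* (the regime in which
discs fail to complete their rim and incisures are absent).

Uncertainty in the measured molar ratios (mean +/- s.d., n = 3 preparations
per genotype) is propagated by Monte Carlo: each ratio is drawn from a
normal distribution truncated at zero and the full prediction chain is
re-run per draw.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from incisure.errors import InvalidInputError

__all__ = [
    "RatioEstimate",
    "MolarRatioTable",
    "RodCensus",
    "DiscGeometry",
    "DiscComposition",
    "RimModel",
    "RimPrediction",
    "UncertaintySummary",
    "disc_surface_area",
    "diameter_from_circumference",
    "rhodopsin_per_disc_reference",
    "scale_rhodopsin_by_area",
    "tetraspanin_per_disc",
    "combine_ratios",
    "tetraspanin_partition",
    "total_rim_length_from_geometry",
    "calibrate_rim_density",
    "predict_rim",
    "predict_genotype",
    "propagate_uncertainty",
    "round_molecules",
    "PROPAGATION_QUANTITIES",
]

#: Ratio names accepted in tables and CSV files.
RATIO_NAMES = (
    "rho_to_prph2",
    "rho_to_rom1",
    "prph2_to_rom1",
    "rho_to_tetraspanin",
)


def _require_positive(name: str, value: float) -> None:
    if not np.isfinite(value) or value <= 0:
        raise InvalidInputError(f"{name} must be positive and finite, got {value!r}")


@dataclass(frozen=True)
class RatioEstimate:
    """A molar ratio with replicate-level uncertainty (mean +/- s.d., n)."""

    mean: float
    sd: float = 0.0
    n: int = 1

    def __post_init__(self):
        _require_positive("ratio mean", self.mean)
        if self.sd < 0:
            raise InvalidInputError(f"ratio sd must be >= 0, got {self.sd}")
        if self.n < 1:
            raise InvalidInputError(f"ratio n must be >= 1, got {self.n}")


@dataclass(frozen=True)
class RodCensus:
    """Whole-rod molecular census: rhodopsin molecules and disc count."""

    rhodopsin_per_rod: float
    discs_per_rod: float

    def __post_init__(self):
        _require_positive("rhodopsin_per_rod", self.rhodopsin_per_rod)
        _require_positive("discs_per_rod", self.discs_per_rod)


class MolarRatioTable:
    """Genotype-wise molar ratios between rhodopsin, peripherin-2 and ROM1.

    Each genotype maps ratio names (a subset of ``RATIO_NAMES``) to
    :class:`RatioEstimate`. When all four ratios are present for a genotype
    the harmonic consistency
    ``1/rho_to_tetraspanin ~= 1/rho_to_prph2 + 1/rho_to_rom1``
    is enforced within ``consistency_tol`` (relative; default 5%, absorbing
    rounding of printed values computed from unrounded replicates).
    """

    def __init__(
        self,
        ratios: Mapping[str, Mapping[str, RatioEstimate]],
        consistency_tol: float = 0.05,
    ):
        self._data: dict[str, dict[str, RatioEstimate]] = {}
        for genotype, entries in ratios.items():
            for name in entries:
                if name not in RATIO_NAMES:
                    raise InvalidInputError(
                        f"unknown ratio {name!r} for genotype {genotype!r}; "
                        f"expected one of {RATIO_NAMES}"
                    )
            self._data[genotype] = dict(entries)
        self.consistency_tol = consistency_tol
        self._check_consistency()

    def _check_consistency(self) -> None:
        for genotype, entries in self._data.items():
            if {"rho_to_prph2", "rho_to_rom1", "rho_to_tetraspanin"} <= set(entries):
                combined = combine_ratios(
                    entries["rho_to_prph2"].mean, entries["rho_to_rom1"].mean
                )
                stated = entries["rho_to_tetraspanin"].mean
                if abs(combined - stated) > self.consistency_tol * stated:
                    raise InvalidInputError(
                        f"{genotype}: combined ratio {combined:.3g} inconsistent "
                        f"with stated rho_to_tetraspanin {stated:.3g} "
                        f"(tolerance {self.consistency_tol:.0%})"
                    )

    @property
    def genotypes(self) -> list[str]:
        return list(self._data)

    def __contains__(self, genotype: str) -> bool:
        return genotype in self._data

    def __getitem__(self, genotype: str) -> dict[str, RatioEstimate]:
        return dict(self._data[genotype])

    def ratio(self, genotype: str, name: str) -> RatioEstimate:
        try:
            entries = self._data[genotype]
        except KeyError:
            raise InvalidInputError(f"unknown genotype {genotype!r}") from None
        if name in entries:
            return entries[name]
        # Derive the combined rhodopsin:tetraspanin ratio when only the
        # per-partner ratios were tabulated.
        if name == "rho_to_tetraspanin" and {
            "rho_to_prph2",
            "rho_to_rom1",
        } <= set(entries):
            mean = combine_ratios(
                entries["rho_to_prph2"].mean, entries["rho_to_rom1"].mean
            )
            return RatioEstimate(mean=mean, sd=0.0, n=min(
                entries["rho_to_prph2"].n, entries["rho_to_rom1"].n))
        raise InvalidInputError(f"genotype {genotype!r} has no ratio {name!r}")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, **kwargs) -> "MolarRatioTable":
        """Build from a long table with columns genotype, quantity, mean, sd, n."""
        required = {"genotype", "quantity", "mean"}
        missing = required - set(frame.columns)
        if missing:
            raise InvalidInputError(f"ratio table missing columns: {sorted(missing)}")
        data: dict[str, dict[str, RatioEstimate]] = {}
        for _, row in frame.iterrows():
            est = RatioEstimate(
                mean=float(row["mean"]),
                sd=float(row.get("sd", 0.0) or 0.0),
                n=int(row.get("n", 1) or 1),
            )
            data.setdefault(str(row["genotype"]), {})[str(row["quantity"])] = est
        return cls(data, **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "MolarRatioTable":
        return cls.from_frame(pd.read_csv(path), **kwargs)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"genotype": g, "quantity": q, "mean": e.mean, "sd": e.sd, "n": e.n}
            for g, entries in self._data.items()
            for q, e in entries.items()
        ]
        return pd.DataFrame(rows, columns=["genotype", "quantity", "mean", "sd", "n"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class DiscGeometry:
    """Planform geometry of one disc.

    Circumference is treated as the primary measurement when a geometry is
    built with :meth:`from_circumference`; the diameter is then derived as
    ``C / pi``. ``measured_incisure_fraction`` is incisure length divided by
    diameter and may exceed 1 (incisures can be longer than the diameter).
    """

    diameter: float
    circumference: float
    surface_area: float
    measured_incisure_fraction: float | None = None

    def __post_init__(self):
        _require_positive("diameter", self.diameter)
        if not math.isclose(self.circumference, math.pi * self.diameter, rel_tol=1e-9):
            raise InvalidInputError("circumference must equal pi * diameter")
        if not math.isclose(
            self.surface_area, disc_surface_area(self.diameter), rel_tol=1e-9
        ):
            raise InvalidInputError("surface_area must equal 2 * pi * (d/2)^2")
        f = self.measured_incisure_fraction
        if f is not None and f < 0:
            raise InvalidInputError(f"incisure fraction must be >= 0, got {f}")

    @classmethod
    def from_diameter(
        cls, diameter: float, measured_incisure_fraction: float | None = None
    ) -> "DiscGeometry":
        _require_positive("diameter", diameter)
        return cls(
            diameter=diameter,
            circumference=math.pi * diameter,
            surface_area=disc_surface_area(diameter),
            measured_incisure_fraction=measured_incisure_fraction,
        )

    @classmethod
    def from_circumference(
        cls, circumference: float, measured_incisure_fraction: float | None = None
    ) -> "DiscGeometry":
        d = diameter_from_circumference(circumference)
        return cls(
            diameter=d,
            circumference=circumference,
            surface_area=disc_surface_area(d),
            measured_incisure_fraction=measured_incisure_fraction,
        )


@dataclass(frozen=True)
class DiscComposition:
    """Molecule counts per disc, carried as reals; round only for display."""

    rhodopsin_per_disc: float
    tetraspanin_per_disc: float

    def __post_init__(self):
        _require_positive("rhodopsin_per_disc", self.rhodopsin_per_disc)
        _require_positive("tetraspanin_per_disc", self.tetraspanin_per_disc)


@dataclass(frozen=True)
class RimModel:
    """Rim linear density calibrated on one genotype (molecules per um)."""

    rim_linear_density: float
    calibration_genotype: str = "WT"

    def __post_init__(self):
        _require_positive("rim_linear_density", self.rim_linear_density)


@dataclass(frozen=True)
class RimPrediction:
    """Predicted rim allocation for one disc.

    ``total_rim_length = circumference + 2 * incisure_length`` when the
    tetraspanin budget suffices to enclose the disc; otherwise the incisure
    is zero, ``enclosure_deficit`` is set and ``deficit_magnitude`` is the
    missing rim length (um).
    """

    total_rim_length: float
    incisure_length: float
    incisure_fraction: float
    enclosure_deficit: bool
    deficit_magnitude: float = 0.0


@dataclass(frozen=True)
class UncertaintySummary:
    """Monte-Carlo propagation result: point estimate and percentile CI."""

    quantity: str
    point_estimate: float
    ci_low: float
    ci_high: float
    n_draws: int
    seed: int
    ci_level: float = 0.95


def round_molecules(count: float, nearest: int = 10) -> int:
    """Round a molecule count for display (default nearest 10, '~5,910' style)."""
    return int(round(count / nearest) * nearest)


def disc_surface_area(d: float) -> float:
    """Membrane surface area of one disc, both lamellar faces: 2*pi*(d/2)^2."""
    _require_positive("diameter", d)
    return 2.0 * math.pi * (d / 2.0) ** 2


def diameter_from_circumference(C: float) -> float:
    """Diameter of a circular disc from its measured circumference: C / pi."""
    _require_positive("circumference", C)
    return C / math.pi


def rhodopsin_per_disc_reference(census: RodCensus) -> float:
    """Rhodopsin molecules per disc: whole-rod count divided by disc count."""
    return census.rhodopsin_per_rod / census.discs_per_rod


def scale_rhodopsin_by_area(
    ref_count: float, ref_area: float, target_area: float
) -> float:
    """Scale a rhodopsin count to another disc area at constant packing density."""
    _require_positive("ref_count", ref_count)
    _require_positive("ref_area", ref_area)
    _require_positive("target_area", target_area)
    return ref_count * target_area / ref_area


def tetraspanin_per_disc(rho_count: float, rho_to_tetraspanin: float) -> float:
    """Tetraspanin (peripherin-2 + ROM1) molecules per disc from the molar ratio."""
    _require_positive("rho_count", rho_count)
    _require_positive("rho_to_tetraspanin", rho_to_tetraspanin)
    return rho_count / rho_to_tetraspanin


def combine_ratios(rho_to_prph2: float, rho_to_rom1: float) -> float:
    """Combined rhodopsin:(peripherin-2 + ROM1) ratio.

    Harmonic combination: with R rhodopsins, P = R/a peripherin-2 and
    T = R/b ROM1 molecules, R/(P + T) = 1 / (1/a + 1/b) = a*b/(a + b).
    """
    _require_positive("rho_to_prph2", rho_to_prph2)
    if not math.isinf(rho_to_rom1):
        _require_positive("rho_to_rom1", rho_to_rom1)
        return 1.0 / (1.0 / rho_to_prph2 + 1.0 / rho_to_rom1)
    return rho_to_prph2


def tetraspanin_partition(rho_to_prph2: float, rho_to_rom1: float) -> float:
    """Peripherin-2:ROM1 ratio implied by the two rhodopsin-relative ratios."""
    _require_positive("rho_to_prph2", rho_to_prph2)
    _require_positive("rho_to_rom1", rho_to_rom1)
    return rho_to_rom1 / rho_to_prph2


def total_rim_length_from_geometry(d: float, incisure_fraction: float) -> float:
    """Total rim length from diameter and incisure fraction.

    The incisure is lined by two apposed rim edges, so it contributes twice
    its length: ``L_rim = pi*d + 2*f*d``.
    """
    _require_positive("diameter", d)
    if incisure_fraction < 0:
        raise InvalidInputError(
            f"incisure_fraction must be >= 0, got {incisure_fraction}"
        )
    return math.pi * d + 2.0 * incisure_fraction * d


def calibrate_rim_density(
    tet_count: float, total_rim_length: float, calibration_genotype: str = "WT"
) -> RimModel:
    """Rim linear density: tetraspanin molecules per um of rim.

    Assumes all tetraspanins of a fully enclosed disc sit in the rim.
    """
    _require_positive("tet_count", tet_count)
    _require_positive("total_rim_length", total_rim_length)
    return RimModel(
        rim_linear_density=tet_count / total_rim_length,
        calibration_genotype=calibration_genotype,
    )


def predict_rim(
    tet_count: float, model: RimModel, geometry: DiscGeometry
) -> RimPrediction:
    """Allocate the tetraspanin budget of a disc to circumference and incisure.

    ``L_rim = tet_count / lambda``. Budget beyond the circumference forms the
    incisure at half the surplus (two apposed edges); a budget below the
    circumference cannot enclose the disc and is reported as a deficit with
    zero incisure rather than a negative length.
    """
    _require_positive("tet_count", tet_count)
    L_rim = tet_count / model.rim_linear_density
    C = geometry.circumference
    d = geometry.diameter
    if L_rim >= C:
        L_inc = (L_rim - C) / 2.0
        return RimPrediction(
            total_rim_length=L_rim,
            incisure_length=L_inc,
            incisure_fraction=L_inc / d,
            enclosure_deficit=False,
            deficit_magnitude=0.0,
        )
    return RimPrediction(
        total_rim_length=L_rim,
        incisure_length=0.0,
        incisure_fraction=0.0,
        enclosure_deficit=True,
        deficit_magnitude=C - L_rim,
    )


# --------------------------------------------------------------------------
# Full prediction chain


def _chain(
    census: RodCensus,
    calib_geometry: DiscGeometry,
    calib_ratio: float | np.ndarray,
    target_geometry: DiscGeometry,
    target_ratio: float | np.ndarray,
) -> dict[str, float | np.ndarray]:
    """Run the full calibration + prediction chain; vectorizes over ratios.

    Calibration genotype: per-disc rhodopsin from the rod census, tetraspanin
    budget from its ratio, rim density from its measured total rim length.
    Target genotype: rhodopsin scaled by area, tetraspanin budget from its
    ratio, rim length and incisure from the calibrated density.
    """
    if calib_geometry.measured_incisure_fraction is None:
        raise InvalidInputError(
            "calibration geometry requires measured_incisure_fraction"
        )
    rho_ref = rhodopsin_per_disc_reference(census)
    L_rim_calib = total_rim_length_from_geometry(
        calib_geometry.diameter, calib_geometry.measured_incisure_fraction
    )
    tet_calib = rho_ref / calib_ratio
    lam = tet_calib / L_rim_calib

    rho_target = (
        rho_ref * target_geometry.surface_area / calib_geometry.surface_area
    )
    tet_target = rho_target / target_ratio
    L_rim = tet_target / lam
    C = target_geometry.circumference
    d = target_geometry.diameter
    L_inc = np.maximum(L_rim - C, 0.0) / 2.0
    deficit = np.maximum(C - L_rim, 0.0)
    return {
        "rhodopsin_per_disc": rho_target,
        "tetraspanin_per_disc": tet_target,
        "rim_linear_density": lam,
        "total_rim_length": L_rim,
        "incisure_length": L_inc,
        "incisure_fraction": L_inc / d,
        "deficit_magnitude": deficit,
    }


PROPAGATION_QUANTITIES = (
    "rhodopsin_per_disc",
    "tetraspanin_per_disc",
    "rim_linear_density",
    "total_rim_length",
    "incisure_length",
    "incisure_fraction",
    "deficit_magnitude",
)


def predict_genotype(
    ratios: MolarRatioTable,
    census: RodCensus,
    geometries: Mapping[str, DiscGeometry],
    genotype: str,
    calibration_genotype: str = "WT",
) -> dict:
    """Full per-genotype prediction record (composition, model, prediction)."""
    if calibration_genotype not in geometries:
        raise InvalidInputError(
            f"no geometry for calibration genotype {calibration_genotype!r}"
        )
    if genotype not in geometries:
        raise InvalidInputError(f"no geometry for genotype {genotype!r}")
    out = _chain(
        census,
        geometries[calibration_genotype],
        ratios.ratio(calibration_genotype, "rho_to_tetraspanin").mean,
        geometries[genotype],
        ratios.ratio(genotype, "rho_to_tetraspanin").mean,
    )
    geom = geometries[genotype]
    composition = DiscComposition(
        rhodopsin_per_disc=float(out["rhodopsin_per_disc"]),
        tetraspanin_per_disc=float(out["tetraspanin_per_disc"]),
    )
    model = RimModel(
        rim_linear_density=float(out["rim_linear_density"]),
        calibration_genotype=calibration_genotype,
    )
    prediction = predict_rim(composition.tetraspanin_per_disc, model, geom)
    return {
        "genotype": genotype,
        "geometry": geom,
        "composition": composition,
        "model": model,
        "prediction": prediction,
    }


def _draw_truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, size: int
) -> np.ndarray:
    """Draws from N(mean, sd) truncated at zero (ratios are positive)."""
    if sd == 0:
        return np.full(size, mean)
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size,
                               random_state=rng)


def propagate_uncertainty(
    ratios: MolarRatioTable,
    census: RodCensus,
    geometries: Mapping[str, DiscGeometry],
    quantity: str = "incisure_fraction",
    genotype: str | None = None,
    calibration_genotype: str = "WT",
    n_draws: int = 10_000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> UncertaintySummary:
    """Monte-Carlo propagation of ratio uncertainty through the chain.

    Each genotype's rhodopsin:tetraspanin ratio is drawn independently from
    a normal truncated at zero with the tabulated mean and s.d.; the full
    calibration + prediction chain is re-run per draw. The point estimate is
    the chain evaluated at the means; the interval is the percentile CI of
    the draws at ``ci_level``. Deterministic for a fixed seed.
    """
    if quantity not in PROPAGATION_QUANTITIES:
        raise InvalidInputError(
            f"unknown quantity {quantity!r}; expected one of "
            f"{PROPAGATION_QUANTITIES}"
        )
    if n_draws < 1:
        raise InvalidInputError(f"n_draws must be >= 1, got {n_draws}")
    if genotype is None:
        candidates = [g for g in geometries if g != calibration_genotype]
        genotype = candidates[0] if candidates else calibration_genotype
    calib_est = ratios.ratio(calibration_genotype, "rho_to_tetraspanin")
    target_est = ratios.ratio(genotype, "rho_to_tetraspanin")
    calib_geom = geometries[calibration_genotype]
    target_geom = geometries[genotype]

    point = float(
        _chain(census, calib_geom, calib_est.mean, target_geom, target_est.mean)[
            quantity
        ]
    )
    rng = np.random.default_rng(seed)
    calib_draws = _draw_truncated_normal(rng, calib_est.mean, calib_est.sd, n_draws)
    target_draws = _draw_truncated_normal(
        rng, target_est.mean, target_est.sd, n_draws
    )
    values = np.asarray(
        _chain(census, calib_geom, calib_draws, target_geom, target_draws)[quantity],
        dtype=float,
    )
    alpha = (1.0 - ci_level) / 2.0
    lo, hi = np.percentile(values, [100 * alpha, 100 * (1 - alpha)])
    return UncertaintySummary(
        quantity=quantity,
        point_estimate=point,
        ci_low=float(lo),
        ci_high=float(hi),
        n_draws=n_draws,
        seed=seed,
        ci_level=ci_level,
    )
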
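"""Pipeline configuration: defaults, loading, validation.

A configuration is a plain mapping (YAML or JSON on disk) with a mandatory
global ``seed``, a rod ``census``, and per-genotype blocks carrying the
molar ratios, the disc geometry (diameter or circumference primary) and an
optional synthetic-cohort block. Validation collects every offending key
before raising, so a bad config reports all its problems at once.
"""

from __future__ import annotations

import copy
import json
from pathlib import Path
from typing import Any, Mapping

import yaml

from incisure.errors import ConfigError
from incisure.stoichiometry import (
    DiscGeometry,
    MolarRatioTable,
    RatioEstimate,
    RodCensus,
)

__all__ = ["default_config", "load_config", "validate_config", "parse_config"]


def default_config() -> dict:
    """Mouse WT vs rhodopsin-hemizygote study conditions.

    Ratios are the tabulated mass-spectrometry means (mean, s.d., n = 3
    preparations per genotype); the census is ~60 million rhodopsins and
    ~800 discs per rod; WT geometry is a 1.5 um disc with a 50% incisure,
    and the hemizygote is specified by its measured 3.36 um circumference.
    The synthetic cohorts mirror the imaging design of three animals per
    genotype.
    """
    return {
        "seed": 0,
        "calibration_genotype": "WT",
        "census": {"rhodopsin_per_rod": 6.0e7, "discs_per_rod": 800},
        "uncertainty": {"n_draws": 10_000, "ci_level": 0.95},
        "detection": {
            "closing_radius": 15,
            "min_incisure_length_fraction": 0.03,
            "min_component_area": 20,
        },
        "genotypes": {
            "WT": {
                "ratios": {
                    "rho_to_prph2": {"mean": 18.2, "sd": 0.6, "n": 3},
                    "rho_to_rom1": {"mean": 42.2, "sd": 0.6, "n": 3},
                    "prph2_to_rom1": {"mean": 2.3, "sd": 0.1, "n": 3},
                    "rho_to_tetraspanin": {"mean": 12.7, "sd": 0.4, "n": 3},
                },
                "geometry": {"diameter": 1.5, "incisure_fraction": 0.5},
                "synthetic": {
                    "n_animals": 3,
                    "discs_per_animal": 8,
                    "pixel_size": 3.0,
                    "noise_sigma": 8.0,
                    "diameter_sd": 0.04,
                    "fraction_sd": 0.02,
                    "incisures": [
                        {
                            "angle": 90.0,
                            "length_fraction": 0.5,
                            "width": 30.0,
                            "shape": "straight",
                        }
                    ],
                },
            },
            "Rho+/-": {
                "ratios": {
                    "rho_to_prph2": {"mean": 8.5, "sd": 1.5, "n": 3},
                    "rho_to_rom1": {"mean": 21.6, "sd": 3.7, "n": 3},
                    "prph2_to_rom1": {"mean": 2.6, "sd": 0.6, "n": 3},
                    "rho_to_tetraspanin": {"mean": 6.0, "sd": 0.8, "n": 3},
                },
                "geometry": {"circumference": 3.36},
                "synthetic": {
                    "n_animals": 3,
                    "discs_per_animal": 8,
                    "pixel_size": 3.0,
                    "noise_sigma": 8.0,
                    "diameter_sd": 0.03,
                    "fraction_sd": 0.05,
                    "incisures": [
                        {
                            "angle": 90.0,
                            "length_fraction": 1.3,
                            "width": 30.0,
                            "shape": "twisted",
                        }
                    ],
                },
            },
        },
    }


def load_config(path: str | Path) -> dict:
    """Read a YAML (or JSON) config file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def validate_config(config: Mapping[str, Any]) -> list[str]:
    """Return a list of problems; empty when the config is valid."""
    problems: list[str] = []
    if not isinstance(config, Mapping):
        return ["config must be a mapping"]
    if "seed" not in config:
        problems.append("seed: missing (a global seed is mandatory)")
    elif not isinstance(config["seed"], int):
        problems.append("seed: must be an integer")
    census = config.get("census")
    if not isinstance(census, Mapping):
        problems.append("census: missing or not a mapping")
    else:
        for key in ("rhodopsin_per_rod", "discs_per_rod"):
            v = census.get(key)
            if not isinstance(v, (int, float)) or v <= 0:
                problems.append(f"census.{key}: must be a positive number")
    genotypes = config.get("genotypes")
    if not isinstance(genotypes, Mapping) or not genotypes:
        problems.append("genotypes: at least one genotype is required")
        genotypes = {}
    calib = config.get("calibration_genotype", "WT")
    if genotypes and calib not in genotypes:
        problems.append(
            f"calibration_genotype: {calib!r} not among genotypes"
        )
    for name, block in genotypes.items():
        prefix = f"genotypes.{name}"
        if not isinstance(block, Mapping):
            problems.append(f"{prefix}: must be a mapping")
            continue
        geom = block.get("geometry")
        if not isinstance(geom, Mapping):
            problems.append(f"{prefix}.geometry: missing or not a mapping")
        elif "diameter" not in geom and "circumference" not in geom:
            problems.append(
                f"{prefix}.geometry: needs 'diameter' or 'circumference'"
            )
        ratios = block.get("ratios")
        if not isinstance(ratios, Mapping) or not ratios:
            problems.append(f"{prefix}.ratios: missing or empty")
        else:
            for rname, est in ratios.items():
                if not isinstance(est, Mapping) or "mean" not in est:
                    problems.append(f"{prefix}.ratios.{rname}: needs a 'mean'")
                elif est["mean"] <= 0:
                    problems.append(f"{prefix}.ratios.{rname}.mean: must be > 0")
                elif est.get("sd", 0) < 0:
                    problems.append(f"{prefix}.ratios.{rname}.sd: must be >= 0")
    if genotypes and calib in genotypes and isinstance(genotypes[calib], Mapping):
        geom = genotypes[calib].get("geometry", {})
        if isinstance(geom, Mapping) and "incisure_fraction" not in geom:
            problems.append(
                f"genotypes.{calib}.geometry.incisure_fraction: required for "
                "the calibration genotype"
            )
    return problems


def parse_config(config: Mapping[str, Any]):
    """Validate and materialize a config into model objects.

    Returns ``(config, census, ratio_table, geometries)`` where geometries
    built from a ``circumference`` key treat it as the primary measurement.
    """
    problems = validate_config(config)
    if problems:
        raise ConfigError(problems)
    config = copy.deepcopy(dict(config))
    census = RodCensus(
        rhodopsin_per_rod=float(config["census"]["rhodopsin_per_rod"]),
        discs_per_rod=float(config["census"]["discs_per_rod"]),
    )
    ratio_data = {
        name: {
            rname: RatioEstimate(
                mean=float(est["mean"]),
                sd=float(est.get("sd", 0.0)),
                n=int(est.get("n", 1)),
            )
            for rname, est in block["ratios"].items()
        }
        for name, block in config["genotypes"].items()
    }
    ratios = MolarRatioTable(ratio_data)
    geometries = {}
    for name, block in config["genotypes"].items():
        geom = block["geometry"]
        f = geom.get("incisure_fraction")
        if "circumference" in geom:
            geometries[name] = DiscGeometry.from_circumference(
                float(geom["circumference"]), measured_incisure_fraction=f
            )
        else:
            geometries[name] = DiscGeometry.from_diameter(
                float(geom["diameter"]), measured_incisure_fraction=f
            )
    return config, census, ratios, geometries
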
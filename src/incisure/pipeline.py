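"""End-to-end pipeline: predict, generate, measure, aggregate, report.

``run_pipeline`` takes a configuration (see :mod:`incisure.config`) and

1. runs the stoichiometric prediction chain for every genotype, with
   Monte-Carlo uncertainty on the incisure fraction;
2. renders a synthetic cohort per genotype (several animals, several discs
   each) when the genotype carries a ``synthetic`` block;
3. measures every rendered disc with the morphometry stage;
4. aggregates per animal, compares diameters between the first two
   genotypes (unpaired t-test on per-animal means) and summarizes incisure
   presence with exact binomial CIs;
5. compares measured against predicted incisure fractions per genotype.

The pipeline performs a single group comparison and applies no
multiple-testing correction; the report says so explicitly. Output is a
JSON report plus flat CSV mirrors, a pure function of config + seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import replace
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from incisure import cohort as cohort_mod
from incisure import stoichiometry as stoich
from incisure.config import parse_config
from incisure.morphometry import DetectionParams, summarize_disc
from incisure.synthetic import (
    DiscSpec,
    IncisureSpec,
    render_disc_section,
    sample_disc_specs,
)

__all__ = ["run_pipeline", "predictions_frame"]

logger = logging.getLogger("incisure.pipeline")


def _detection_params(config: Mapping[str, Any]) -> DetectionParams:
    block = config.get("detection", {})
    return DetectionParams(
        threshold_method=block.get("threshold_method", "otsu"),
        fixed_threshold=block.get("fixed_threshold"),
        closing_radius=int(block.get("closing_radius", 15)),
        min_incisure_length_fraction=float(
            block.get("min_incisure_length_fraction", 0.03)
        ),
        min_component_area=int(block.get("min_component_area", 20)),
    )


def _disc_spec(genotype_block: Mapping[str, Any], diameter: float) -> DiscSpec:
    syn = genotype_block["synthetic"]
    incisures = tuple(
        IncisureSpec(
            angle=float(i.get("angle", 90.0)),
            length_fraction=float(i.get("length_fraction", 0.5)),
            width=float(i.get("width", 30.0)),
            shape=i.get("shape", "straight"),
        )
        for i in syn.get("incisures", [])
    )
    return DiscSpec(
        diameter=diameter,
        pixel_size=float(syn.get("pixel_size", 3.0)),
        incisures=incisures,
        noise_sigma=float(syn.get("noise_sigma", 8.0)),
    )


def predictions_frame(records: list[dict]) -> pd.DataFrame:
    """Flatten per-genotype prediction records into a table."""
    rows = []
    for rec in records:
        pred = rec["prediction"]
        comp = rec["composition"]
        geom = rec["geometry"]
        rows.append(
            {
                "genotype": rec["genotype"],
                "diameter_um": geom.diameter,
                "circumference_um": geom.circumference,
                "surface_area_um2": geom.surface_area,
                "rhodopsin_per_disc": comp.rhodopsin_per_disc,
                "tetraspanin_per_disc": comp.tetraspanin_per_disc,
                "rim_density_per_um": rec["model"].rim_linear_density,
                "total_rim_length_um": pred.total_rim_length,
                "incisure_length_um": pred.incisure_length,
                "incisure_fraction": pred.incisure_fraction,
                "enclosure_deficit": pred.enclosure_deficit,
                "deficit_magnitude_um": pred.deficit_magnitude,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(
    config: Mapping[str, Any], outdir: str | Path | None = None
) -> dict:
    """Execute the full pipeline; returns the report dict.

    When ``outdir`` is given (or set in the config) the JSON report, the
    cohort CSV, the per-animal means CSV, the predictions CSV and a run log
    are written there.
    """
    config, census, ratios, geometries = parse_config(config)
    seed = int(config["seed"])
    calib = config.get("calibration_genotype", "WT")
    outdir = outdir or config.get("outdir")
    params = _detection_params(config)

    log_lines: list[str] = []

    def log(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    log(f"pipeline start: seed={seed}, genotypes={list(geometries)}")

    # 1. stoichiometric predictions + uncertainty
    prediction_records = [
        stoich.predict_genotype(ratios, census, geometries, g, calib)
        for g in geometries
    ]
    unc_cfg = config.get("uncertainty", {})
    uncertainty = {}
    for g in geometries:
        summary = stoich.propagate_uncertainty(
            ratios,
            census,
            geometries,
            quantity="incisure_fraction",
            genotype=g,
            calibration_genotype=calib,
            n_draws=int(unc_cfg.get("n_draws", 10_000)),
            seed=seed,
            ci_level=float(unc_cfg.get("ci_level", 0.95)),
        )
        uncertainty[g] = dataclasses.asdict(summary)
    pred_frame = predictions_frame(prediction_records)
    log("predictions computed for all genotypes")

    # 2-3. synthetic cohort + morphometry
    cohort_rows = []
    root_ss = np.random.SeedSequence(seed)
    for gi, (g, block) in enumerate(sorted(config["genotypes"].items())):
        if "synthetic" not in block:
            continue
        syn = block["synthetic"]
        base = _disc_spec(block, geometries[g].diameter)
        n_animals = int(syn.get("n_animals", 3))
        per_animal = int(syn.get("discs_per_animal", 8))
        for ai in range(n_animals):
            ss = np.random.SeedSequence((seed, gi, ai))
            rng = np.random.default_rng(ss)
            specs = sample_disc_specs(
                per_animal,
                base,
                rng,
                diameter_sd=float(syn.get("diameter_sd", 0.04)),
                fraction_sd=float(syn.get("fraction_sd", 0.02)),
            )
            disc_seeds = ss.generate_state(per_animal) % (2**31)
            for di, (spec, dseed) in enumerate(zip(specs, disc_seeds)):
                section = render_disc_section(spec, seed=int(dseed))
                result = summarize_disc(
                    section.image, params, pixel_size=spec.pixel_size
                )
                cohort_rows.append(
                    {
                        "genotype": g,
                        "animal_id": f"{g}-{ai + 1}",
                        "disc_id": f"disc-{di:03d}",
                        "diameter": result.diameter,
                        "incisure_fraction": (
                            max(result.incisure_fractions)
                            if result.incisure_fractions
                            else 0.0
                        ),
                        "has_incisure": result.has_incisure,
                        "incisure_count": result.incisure_count,
                        "true_diameter": spec.diameter,
                        "true_fraction": (
                            max(i.length_fraction for i in spec.incisures)
                            if spec.incisures
                            else 0.0
                        ),
                    }
                )
        log(f"{g}: rendered and measured {n_animals} x {per_animal} discs")

    report: dict[str, Any] = {
        "seed": seed,
        "calibration_genotype": calib,
        "predictions": pred_frame.to_dict(orient="records"),
        "uncertainty": uncertainty,
        "statistics": {
            "multiple_testing_correction": (
                "none (a single group comparison is performed)"
            )
        },
    }

    cohort_table = None
    means = None
    if cohort_rows:
        cohort_table = cohort_mod.make_cohort_table(cohort_rows)
        means = cohort_mod.per_animal_means(cohort_table, "diameter")
        genos = sorted(cohort_table["genotype"].unique())
        if len(genos) >= 2:
            a, b = genos[0], genos[1]
            cmp = cohort_mod.unpaired_t_test(
                means.loc[means["genotype"] == a, "diameter"],
                means.loc[means["genotype"] == b, "diameter"],
                group_a=a,
                group_b=b,
                welch=bool(config.get("welch", False)),
            )
            report["statistics"]["diameter_t_test"] = dataclasses.asdict(cmp)
        presence = cohort_mod.presence_frequency(cohort_table)
        report["statistics"]["presence"] = [
            dataclasses.asdict(p) for p in presence
        ]
        # 5. measured vs predicted incisure fractions
        comparison = []
        for rec in prediction_records:
            g = rec["genotype"]
            sub = cohort_table[cohort_table["genotype"] == g]
            if len(sub) == 0:
                continue
            comparison.append(
                {
                    "genotype": g,
                    "predicted_incisure_fraction": rec[
                        "prediction"
                    ].incisure_fraction,
                    "measured_incisure_fraction_mean": float(
                        sub["incisure_fraction"].mean()
                    ),
                    "generator_fraction_mean": float(sub["true_fraction"].mean()),
                    "n_discs": int(len(sub)),
                }
            )
        report["measured_vs_predicted"] = comparison
        report["cohort"] = {
            "n_discs": int(len(cohort_table)),
            "n_animals": int(
                cohort_table.groupby(["genotype", "animal_id"]).ngroups
            ),
        }
        log("cohort statistics computed")

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(json.dumps(report, indent=2))
        pred_frame.to_csv(outdir / "predictions.csv", index=False)
        if cohort_table is not None:
            cohort_table.to_csv(outdir / "cohort.csv", index=False)
            means.to_csv(outdir / "per_animal_means.csv", index=False)
        (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
        log(f"report written to {outdir}")
    return report
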
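import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from incisure.stoichiometry import (
    DiscGeometry,
    MolarRatioTable,
    RatioEstimate,
    RodCensus,
)


@pytest.fixture(scope="session")
def ratio_table() -> MolarRatioTable:
    """Measured molar ratios (mean, s.d., n = 3 preparations per genotype)."""
    return MolarRatioTable(
        {
            "WT": {
                "rho_to_prph2": RatioEstimate(18.2, 0.6, 3),
                "rho_to_rom1": RatioEstimate(42.2, 0.6, 3),
                "prph2_to_rom1": RatioEstimate(2.3, 0.1, 3),
                "rho_to_tetraspanin": RatioEstimate(12.7, 0.4, 3),
            },
            "rds/+": {
                "rho_to_prph2": RatioEstimate(30.9, 6.0, 3),
                "rho_to_rom1": RatioEstimate(29.9, 2.0, 3),
                "prph2_to_rom1": RatioEstimate(1.0, 0.2, 3),
                "rho_to_tetraspanin": RatioEstimate(15.1, 1.8, 3),
            },
            "Rho+/-": {
                "rho_to_prph2": RatioEstimate(8.5, 1.5, 3),
                "rho_to_rom1": RatioEstimate(21.6, 3.7, 3),
                "prph2_to_rom1": RatioEstimate(2.6, 0.6, 3),
                "rho_to_tetraspanin": RatioEstimate(6.0, 0.8, 3),
            },
        }
    )


@pytest.fixture(scope="session")
def census() -> RodCensus:
    return RodCensus(rhodopsin_per_rod=6.0e7, discs_per_rod=800)


@pytest.fixture(scope="session")
def geometries() -> dict[str, DiscGeometry]:
    """WT from its diameter; the hemizygote from its measured circumference."""
    return {
        "WT": DiscGeometry.from_diameter(1.5, measured_incisure_fraction=0.5),
        "Rho+/-": DiscGeometry.from_circumference(3.36),
    }


@pytest.fixture(scope="session")
def wt_section():
    from incisure.synthetic import render_disc_section, wt_mouse_spec

    return render_disc_section(wt_mouse_spec(), seed=101)


@pytest.fixture(scope="session")
def wt_clean_section():
    from incisure.synthetic import DiscSpec, IncisureSpec, render_disc_section

    spec = DiscSpec(
        diameter=1.5,
        incisures=(IncisureSpec(length_fraction=0.5),),
        blur_sigma=0.0,
        noise_sigma=0.0,
    )
    return render_disc_section(spec, seed=102)
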
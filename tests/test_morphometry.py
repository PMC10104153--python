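"""Parameter-recovery tests of the morphometry stage against synthetic truth."""

import numpy as np
import pytest

from incisure.errors import InvalidInputError, MorphometryError, SegmentationError
from incisure.morphometry import (
    DetectionParams,
    DiscMask,
    detect_incisures,
    equivalent_diameter,
    measure_incisure_length,
    segment_disc,
    summarize_disc,
)
from incisure.synthetic import (
    DiscSpec,
    IncisureSpec,
    frog_spec,
    render_disc_section,
)

DEFAULTS = DetectionParams()


# ---------------------------------------------------------------------------
# Segmentation


def test_segmentation_matches_generator_mask(wt_clean_section):
    """On a noise- and blur-free render the segmented mask equals the
    generator's internal mask up to a 1-pixel boundary band."""
    sec = wt_clean_section
    mask = segment_disc(sec.image, DEFAULTS, pixel_size=sec.spec.pixel_size)
    diff = mask.mask ^ sec.mask
    from scipy import ndimage

    boundary = sec.mask ^ ndimage.binary_erosion(sec.mask)
    band = ndimage.binary_dilation(boundary, iterations=1)
    assert not (diff & ~band).any()


def test_all_background_image_fails():
    with pytest.raises(SegmentationError):
        segment_disc(np.zeros((64, 64), dtype=np.uint8), DEFAULTS)


def test_two_discs_keeps_larger():
    img = np.zeros((200, 400), dtype=np.uint8)
    rr, cc = np.ogrid[:200, :400]
    img[(rr - 100) ** 2 + (cc - 100) ** 2 <= 60**2] = 200
    img[(rr - 100) ** 2 + (cc - 300) ** 2 <= 30**2] = 200
    mask = segment_disc(img, DEFAULTS)
    assert mask.mask[100, 100] and not mask.mask[100, 300]


def test_constant_image_otsu_fails():
    with pytest.raises(SegmentationError):
        segment_disc(np.full((32, 32), 7, dtype=np.uint8), DEFAULTS)


# ---------------------------------------------------------------------------
# Diameter


def test_equivalent_diameter_perfect_circle():
    size = 520
    rr, cc = np.ogrid[:size, :size]
    mask = (rr - 260) ** 2 + (cc - 260) ** 2 <= 250**2
    d = equivalent_diameter(DiscMask(mask, pixel_size=3.0))
    assert d == pytest.approx(1.5, abs=0.003)


def test_equivalent_diameter_closes_the_slit(wt_clean_section):
    """The diameter is that of the disc, not the disc minus its incisure."""
    sec = wt_clean_section
    mask = DiscMask(sec.mask, pixel_size=sec.spec.pixel_size)
    assert equivalent_diameter(mask) == pytest.approx(1.5, abs=0.005)


def test_equivalent_diameter_unit_invariance():
    rr, cc = np.ogrid[:260, :260]
    small = (rr - 130) ** 2 + (cc - 130) ** 2 <= 125**2
    rr, cc = np.ogrid[:520, :520]
    big = (rr - 260) ** 2 + (cc - 260) ** 2 <= 250**2
    d_small = equivalent_diameter(DiscMask(small, pixel_size=6.0))
    d_big = equivalent_diameter(DiscMask(big, pixel_size=3.0))
    assert d_small == pytest.approx(d_big, rel=0.01)


def test_equivalent_diameter_empty_mask():
    with pytest.raises(InvalidInputError):
        equivalent_diameter(DiscMask(np.zeros((8, 8), bool), pixel_size=3.0))


def test_rho_het_diameter_recovery():
    spec = DiscSpec(
        diameter=1.07,
        incisures=(IncisureSpec(length_fraction=1.3, shape="twisted"),),
        noise_sigma=8.0,
    )
    sec = render_disc_section(spec, seed=21)
    res = summarize_disc(sec.image)
    assert res.diameter == pytest.approx(1.07, abs=0.01)


# ---------------------------------------------------------------------------
# Detection


def test_detect_single_wt_incisure(wt_section):
    mask = segment_disc(wt_section.image, DEFAULTS)
    comps = detect_incisures(mask, DEFAULTS)
    assert len(comps) == 1


def test_detect_nothing_without_incisure():
    sec = render_disc_section(DiscSpec(diameter=1.5, incisures=()), seed=8)
    mask = segment_disc(sec.image, DEFAULTS)
    assert detect_incisures(mask, DEFAULTS) == []


def test_detect_frog_multi_incisures():
    sec = render_disc_section(frog_spec(15), seed=9)
    params = DetectionParams(closing_radius=10)
    res = summarize_disc(sec.image, params, pixel_size=6.0)
    assert res.incisure_count == 15


def test_small_closing_radius_detects_nothing(wt_section):
    """A closing disk smaller than half the slit width cannot bridge it:
    documented no-detection behavior, not an error."""
    params = DetectionParams(closing_radius=2)
    mask = segment_disc(wt_section.image, params)
    assert detect_incisures(mask, params) == []


def test_no_false_positives_across_closing_radii():
    sec = render_disc_section(
        DiscSpec(diameter=1.5, incisures=(), noise_sigma=0.0), seed=10
    )
    for radius in (5, 10, 15, 20):
        params = DetectionParams(closing_radius=radius)
        res = summarize_disc(sec.image, params)
        assert not res.has_incisure


# ---------------------------------------------------------------------------
# Length measurement


def test_straight_length_recovery(wt_section):
    res = summarize_disc(wt_section.image)
    assert len(res.incisure_lengths) == 1
    assert res.incisure_lengths[0] == pytest.approx(
        wt_section.incisures[0].length_um, abs=0.01
    )
    # a straight incisure's chord nearly equals its path length
    assert res.incisure_chords[0] == pytest.approx(
        res.incisure_lengths[0], rel=0.03
    )


def test_single_pixel_component():
    mask = np.zeros((64, 64), bool)
    rr, cc = np.ogrid[:64, :64]
    mask[(rr - 32) ** 2 + (cc - 32) ** 2 <= 20**2] = True
    comp = np.zeros((64, 64), bool)
    comp[32, 12] = True
    m = measure_incisure_length(comp, DiscMask(mask, pixel_size=3.0))
    assert m.length_um == pytest.approx(0.003)


def test_bifurcated_lengths():
    """Stem 0.5 um forking into 0.4 and 0.3 um branches: main path 0.9 um,
    total skeleton 1.2 um, each within 2%."""
    spec = DiscSpec(
        diameter=1.0,
        incisures=(
            IncisureSpec(
                length_fraction=0.9,
                shape="bifurcated",
                stem_fraction=0.5,
                branch_fractions=(0.4, 0.3),
                branch_angle=60.0,
            ),
        ),
        noise_sigma=0.0,
    )
    sec = render_disc_section(spec, seed=12)
    res = summarize_disc(sec.image)
    assert res.incisure_count == 1
    m = res.measurements[0]
    assert m.length_um == pytest.approx(0.9, rel=0.02)
    assert m.total_skeleton_um == pytest.approx(1.2, rel=0.02)
    assert len(m.branch_lengths_um) == 2
    assert m.branch_lengths_um[0] == pytest.approx(0.4, abs=0.025)
    assert m.branch_lengths_um[1] == pytest.approx(0.3, abs=0.025)


def test_rotation_robustness():
    spec = DiscSpec(
        diameter=1.5,
        incisures=(IncisureSpec(angle=37.0, length_fraction=0.5),),
        noise_sigma=8.0,
    )
    sec = render_disc_section(spec, seed=13)
    r0 = summarize_disc(sec.image)
    r90 = summarize_disc(np.rot90(sec.image))
    assert abs(
        max(r0.incisure_fractions) - max(r90.incisure_fractions)
    ) < 0.02
    assert r0.diameter == pytest.approx(r90.diameter, abs=0.005)


def test_summarize_blank_image_reports_stage():
    with pytest.raises(MorphometryError) as err:
        summarize_disc(np.zeros((64, 64), dtype=np.uint8))
    assert err.value.stage == "segmentation"


def test_presence_threshold_applies():
    sec = render_disc_section(
        DiscSpec(diameter=1.5, incisures=(IncisureSpec(length_fraction=0.1),)),
        seed=14,
    )
    low = summarize_disc(sec.image, DetectionParams())
    high = summarize_disc(
        sec.image, DetectionParams(min_incisure_length_fraction=0.5)
    )
    assert low.has_incisure and not high.has_incisure
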
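"""Synthetic tangential-section image generator with exact ground truth.

Renders rod discs as they appear in tangentially sectioned electron
micrographs: a bright filled circle (the disc) on a dark background, with
each incisure carved as a background-intensity slit running from the rim
toward the disc center. Three incisure shapes cover the morphologies seen
across genotypes:

* ``straight`` -- a radial chord, the typical single mouse WT incisure
  (~50% of the disc diameter);
* ``twisted`` -- a sinusoidal perturbation of the radial chord, so the path
  length can exceed the disc diameter (the elongated, convoluted incisures
  of rhodopsin-hemizygous rods);
* ``bifurcated`` -- a stem that forks once into two branches.

Discs with empty incisure lists emulate the peripherin-2-deficient
phenotypes (mouse *rds*/+, frog *prph2* knockout); multi-incisure specs at
larger diameters emulate amphibian discs (up to ~20 incisures).

Every rendered image carries its ground truth: the exact polyline of each
incisure, its in-disc path length in physical units, and the rendered
diameter. Rendering is deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import tifffile
from PIL import Image
from scipy import ndimage, stats
from skimage.draw import line as draw_line
from skimage.morphology import dilation, disk

from incisure.errors import InvalidInputError

__all__ = [
    "IncisureSpec",
    "DiscSpec",
    "IncisureTruth",
    "SyntheticSection",
    "RatioSampleSpec",
    "render_disc_section",
    "render_population",
    "sample_disc_specs",
    "sample_ratio_replicates",
    "wt_mouse_spec",
    "rho_het_spec",
    "rds_het_spec",
    "frog_spec",
]

INCISURE_SHAPES = ("straight", "bifurcated", "twisted")


@dataclass(frozen=True)
class IncisureSpec:
    """One incisure: where it enters the rim and the path it follows.

    ``length_fraction`` is the target in-disc path length divided by the
    disc diameter. For straight and bifurcated incisures it cannot exceed 1
    (the path is a chord); twisted incisures accommodate larger fractions by
    winding. ``angle`` locates the rim entry point in degrees.
    """

    angle: float = 90.0
    length_fraction: float = 0.5
    width: float = 30.0  # nm
    shape: str = "straight"
    branch_angle: float = 50.0  # degrees between the two branches
    waviness_amplitude: float = 80.0  # nm
    waviness_period: float = 400.0  # nm
    # Optional explicit bifurcation layout, as fractions of the diameter.
    stem_fraction: float | None = None
    branch_fractions: tuple[float, float] | None = None

    def __post_init__(self):
        if self.length_fraction < 0:
            raise InvalidInputError(
                f"length_fraction must be >= 0, got {self.length_fraction}"
            )
        if self.width <= 0:
            raise InvalidInputError(f"width must be > 0, got {self.width}")
        if self.shape not in INCISURE_SHAPES:
            raise InvalidInputError(
                f"shape must be one of {INCISURE_SHAPES}, got {self.shape!r}"
            )


@dataclass(frozen=True)
class DiscSpec:
    """One disc to render: geometry, incisures, optics and noise.

    Intensities follow the convention disc = bright, background and
    incisure = dark. ``blur_sigma`` emulates the finite resolution of the
    section image; ``noise_sigma`` is additive Gaussian noise in intensity
    units on an 8-bit scale.
    """

    diameter: float = 1.5  # um
    pixel_size: float = 3.0  # nm / pixel
    incisures: tuple[IncisureSpec, ...] = ()
    foreground: float = 200.0
    background: float = 40.0
    blur_sigma: float = 6.0  # nm
    noise_sigma: float = 0.0
    margin_fraction: float = 0.10

    def __post_init__(self):
        if self.diameter <= 0:
            raise InvalidInputError(f"diameter must be > 0, got {self.diameter}")
        if self.pixel_size <= 0:
            raise InvalidInputError(f"pixel_size must be > 0, got {self.pixel_size}")
        if self.margin_fraction < 0.05:
            raise InvalidInputError(
                f"margin_fraction must be >= 0.05, got {self.margin_fraction}"
            )
        object.__setattr__(self, "incisures", tuple(self.incisures))
        radius_nm = self.diameter * 1000.0 / 2.0
        for inc in self.incisures:
            if inc.width > radius_nm:
                raise InvalidInputError(
                    f"incisure width {inc.width} nm exceeds disc radius "
                    f"{radius_nm:.0f} nm"
                )


@dataclass(frozen=True)
class IncisureTruth:
    """Exact rendered geometry of one incisure."""

    spec: IncisureSpec
    path: np.ndarray  # (N, 2) row/col pixel coordinates, rim to tip
    length_um: float  # in-disc main path length (rim entry to farthest tip)
    total_length_um: float  # includes both branches for bifurcated
    branch_lengths_um: tuple[float, ...] = ()


@dataclass(frozen=True)
class SyntheticSection:
    """Rendered raster plus its ground truth."""

    image: np.ndarray  # uint8, row/col origin top-left
    mask: np.ndarray  # clean boolean disc mask (pre blur/noise)
    spec: DiscSpec
    incisures: tuple[IncisureTruth, ...]
    rendered_diameter_um: float
    seed: int


# --------------------------------------------------------------------------
# Path construction (all coordinates in pixels, row/col)


def _unit(angle_deg: float) -> np.ndarray:
    a = math.radians(angle_deg)
    # row decreases upward; keep simple row/col math
    return np.array([math.sin(a), math.cos(a)])


def _polyline_length(points: np.ndarray) -> float:
    return float(np.sum(np.hypot(*np.diff(points, axis=0).T)))


def _straight_path(
    center: np.ndarray, R: float, angle: float, length_px: float, overshoot: float
) -> np.ndarray:
    """Chord from the rim toward (and possibly past) the center."""
    u = _unit(angle)
    entry = center + R * u
    step = 0.5
    ts = np.arange(-overshoot, length_px + step, step)
    return entry - np.outer(ts, u)


def _twisted_path(
    center: np.ndarray,
    R: float,
    angle: float,
    length_px: float,
    amplitude_px: float,
    period_px: float,
    margin_px: float,
    overshoot: float,
) -> np.ndarray:
    """Sinusoidally perturbed chord whose arc length hits the target.

    The baseline runs from the rim entry through the center; the transverse
    sinusoid starts at zero at the rim so the entry point stays on the rim.
    The baseline extent is solved so that the in-disc arc length equals
    ``length_px``; if the full chord is too short the amplitude is scaled up
    until the target is reachable.
    """
    u = _unit(angle)
    v = np.array([u[1], -u[0]])  # transverse unit
    entry = center + R * u
    step = 0.5
    margin = margin_px
    t_max_chord = 2.0 * R - margin  # tip must not breach the opposite rim

    def build(amp: float, t_end: float) -> np.ndarray:
        ts = np.arange(0.0, t_end + step, step)
        offs = amp * np.sin(2.0 * math.pi * ts / period_px)
        # keep every point (and the carved width around it) inside the disc:
        # at baseline depth t the transverse excursion is bounded by the
        # chord of the radius-(R - margin) circle
        allowed = np.sqrt(np.maximum((R - margin) ** 2 - (R - ts) ** 2, 0.0))
        offs = np.clip(offs, -allowed, allowed)
        return entry - np.outer(ts, u) + np.outer(offs, v)

    amp = amplitude_px
    for _ in range(40):
        full = build(amp, t_max_chord)
        if _polyline_length(full) >= length_px:
            break
        amp *= 1.3
    # binary search the baseline extent, then trim to the exact arc length
    # (the clipped offsets make arc length jump with t_end)
    lo, hi = 0.0, t_max_chord
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        if _polyline_length(build(amp, mid)) < length_px:
            lo = mid
        else:
            hi = mid
    pts = build(amp, hi)
    seg = np.hypot(*np.diff(pts, axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    k = int(np.searchsorted(cum, length_px))
    if 0 < k < len(pts):
        excess = cum[k] - length_px
        frac = 1.0 - excess / max(seg[k - 1], 1e-12)
        last = pts[k - 1] + frac * (pts[k] - pts[k - 1])
        pts = np.vstack([pts[:k], last])
    # prepend the overshoot outside the rim along the inward direction
    ts = np.arange(step, overshoot + step, step)
    pre = entry + np.outer(ts[::-1], u)
    return np.vstack([pre, pts])


def _bifurcated_paths(
    center: np.ndarray,
    R: float,
    angle: float,
    stem_px: float,
    branch_px: tuple[float, float],
    branch_angle: float,
    overshoot: float,
) -> list[np.ndarray]:
    """Stem from the rim, forking once into two branches."""
    u = _unit(angle)
    entry = center + R * u
    step = 0.5
    ts = np.arange(-overshoot, stem_px + step, step)
    stem = entry - np.outer(ts, u)
    fork = entry - stem_px * u
    paths = [stem]
    for sign, blen in zip((+1.0, -1.0), branch_px):
        if blen <= 0:
            continue
        a = angle + 180.0 + sign * branch_angle / 2.0  # inward +/- half-angle
        ub = _unit(a)
        tb = np.arange(0.0, blen + step, step)
        paths.append(fork + np.outer(tb, ub))
    return paths


def _carve(shape: tuple[int, int], paths: Sequence[np.ndarray], radius_px: int
           ) -> np.ndarray:
    """Rasterize polylines and thicken with a disk structuring element."""
    canvas = np.zeros(shape, dtype=bool)
    for pts in paths:
        rr = np.clip(np.round(pts[:, 0]).astype(int), 0, shape[0] - 1)
        cc = np.clip(np.round(pts[:, 1]).astype(int), 0, shape[1] - 1)
        for i in range(len(rr) - 1):  # segments stay continuous at any step size
            lr, lc = draw_line(rr[i], cc[i], rr[i + 1], cc[i + 1])
            canvas[lr, lc] = True
        canvas[rr, cc] = True
    if radius_px >= 1:
        canvas = dilation(canvas, disk(radius_px))
    return canvas


def render_disc_section(spec: DiscSpec, seed: int = 0) -> SyntheticSection:
    """Render one disc section and its ground truth.

    The clean boolean mask (disc minus slits) is built first, then blurred
    with a Gaussian of ``blur_sigma`` and corrupted with additive Gaussian
    noise of ``noise_sigma``; output is 8-bit.
    """
    px = spec.pixel_size
    d_px = spec.diameter * 1000.0 / px
    R = d_px / 2.0
    size = int(math.ceil(d_px * (1.0 + 2.0 * spec.margin_fraction)))
    center = np.array([size / 2.0, size / 2.0])

    rows, cols = np.ogrid[:size, :size]
    dist2 = (rows - center[0]) ** 2 + (cols - center[1]) ** 2
    disc = dist2 <= R**2
    rendered_diameter_um = 2.0 * math.sqrt(disc.sum() / math.pi) * px / 1000.0

    truths: list[IncisureTruth] = []
    mask = disc.copy()
    for inc in spec.incisures:
        width_px = inc.width / px
        overshoot = width_px + 2.0
        length_px = inc.length_fraction * d_px
        if inc.shape == "straight":
            if inc.length_fraction > 1.0:
                raise InvalidInputError(
                    "straight incisures cannot exceed the disc diameter; "
                    "use shape='twisted'"
                )
            # A full-diameter slit would sever the 2-D mask; stop the carved
            # tip short of the opposite rim ("nearly the entire disc
            # diameter"), leaving a bridge that survives blur and noise.
            # The recorded ground truth is the rendered length.
            cap = d_px - width_px - 8.0
            eff = min(length_px, cap)
            paths = [_straight_path(center, R, inc.angle, eff, overshoot)]
            main = eff
            total = eff
            branches: tuple[float, ...] = ()
        elif inc.shape == "twisted":
            pts = _twisted_path(
                center,
                R,
                inc.angle,
                length_px,
                inc.waviness_amplitude / px,
                inc.waviness_period / px,
                # keep a rim band that survives carving, blur and threshold
                width_px / 2.0 + 4.0 + 3.0 * spec.blur_sigma / px,
                overshoot,
            )
            paths = [pts]
            inside = np.hypot(*(pts - center).T) <= R
            main = _polyline_length(pts[inside])
            total = main
            branches = ()
        else:  # bifurcated
            stem_f = inc.stem_fraction
            branch_f = inc.branch_fractions
            if stem_f is None:
                stem_f = inc.length_fraction / 2.0
            if branch_f is None:
                half = inc.length_fraction / 2.0
                branch_f = (half, half)
            stem_px = stem_f * d_px
            branch_px = (branch_f[0] * d_px, branch_f[1] * d_px)
            if stem_f + max(branch_f) > 1.0:
                raise InvalidInputError(
                    "bifurcated incisure does not fit inside the disc"
                )
            paths = _bifurcated_paths(
                center, R, inc.angle, stem_px, branch_px, inc.branch_angle,
                overshoot,
            )
            branches = tuple(b / d_px * spec.diameter for b in branch_px)
            main = stem_px + max(branch_px)
            total = stem_px + sum(branch_px)
        slit = _carve(mask.shape, paths, max(int(round(width_px / 2.0)), 1))
        mask &= ~slit
        truths.append(
            IncisureTruth(
                spec=inc,
                path=np.vstack(paths),
                length_um=main * px / 1000.0,
                total_length_um=total * px / 1000.0,
                branch_lengths_um=branches,
            )
        )

    image = np.where(mask, spec.foreground, spec.background).astype(float)
    if spec.blur_sigma > 0:
        image = ndimage.gaussian_filter(image, sigma=spec.blur_sigma / px)
    rng = np.random.default_rng(seed)
    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, image.shape)
    image = np.clip(np.round(image), 0, 255).astype(np.uint8)
    return SyntheticSection(
        image=image,
        mask=mask,
        spec=spec,
        incisures=tuple(truths),
        rendered_diameter_um=rendered_diameter_um,
        seed=seed,
    )


# --------------------------------------------------------------------------
# Archetype specs


def wt_mouse_spec(noise_sigma: float = 8.0) -> DiscSpec:
    """Mouse WT: 1.5 um disc with one straight incisure at half the diameter."""
    return DiscSpec(
        diameter=1.5,
        incisures=(IncisureSpec(length_fraction=0.5),),
        noise_sigma=noise_sigma,
    )


def rho_het_spec(noise_sigma: float = 8.0) -> DiscSpec:
    """Rhodopsin-hemizygote: small disc, long twisted incisure (>100% of d)."""
    return DiscSpec(
        diameter=1.07,
        incisures=(IncisureSpec(length_fraction=1.3, shape="twisted"),),
        noise_sigma=noise_sigma,
    )


def rds_het_spec(noise_sigma: float = 8.0) -> DiscSpec:
    """Peripherin-2 heterozygote: no incisure (enclosure-deficit phenotype)."""
    return DiscSpec(diameter=1.5, incisures=(), noise_sigma=noise_sigma)


def frog_spec(n_incisures: int = 15, noise_sigma: float = 8.0) -> DiscSpec:
    """Amphibian rod: large disc carrying many short radial incisures."""
    angles = np.linspace(0.0, 360.0, n_incisures, endpoint=False)
    incisures = tuple(
        IncisureSpec(angle=float(a), length_fraction=0.25, width=40.0)
        for a in angles
    )
    return DiscSpec(
        diameter=6.0, pixel_size=6.0, incisures=incisures, noise_sigma=noise_sigma
    )


# --------------------------------------------------------------------------
# Populations


def sample_disc_specs(
    n: int,
    base: DiscSpec,
    rng: np.random.Generator,
    diameter_sd: float = 0.05,
    fraction_sd: float = 0.03,
) -> list[DiscSpec]:
    """Jitter diameter and incisure fractions around a base spec."""
    specs = []
    for _ in range(n):
        d = max(float(rng.normal(base.diameter, diameter_sd)), 0.2)
        incs = tuple(
            replace(
                inc,
                length_fraction=max(
                    float(rng.normal(inc.length_fraction, fraction_sd)), 0.0
                ),
            )
            for inc in base.incisures
        )
        specs.append(replace(base, diameter=d, incisures=incs))
    return specs


def render_population(
    specs: Sequence[DiscSpec],
    seed: int,
    outdir: str | Path | None = None,
    fmt: str = "tiff",
    prefix: str = "disc",
) -> tuple[list[SyntheticSection], pd.DataFrame]:
    """Render a collection of discs; optionally write images and the truth table.

    Per-image seeds are spawned deterministically from the global seed. When
    ``outdir`` is given, images are written as TIFF (default) or PNG and the
    ground-truth table as ``ground_truth.csv``.
    """
    if len(specs) < 1:
        raise InvalidInputError("population must contain at least one spec")
    if fmt not in ("tiff", "png"):
        raise InvalidInputError(f"fmt must be 'tiff' or 'png', got {fmt!r}")
    child_seeds = np.random.SeedSequence(seed).generate_state(len(specs)) % (2**31)
    sections = []
    rows = []
    for i, (spec, s) in enumerate(zip(specs, child_seeds)):
        section = render_disc_section(spec, seed=int(s))
        sections.append(section)
        name = f"{prefix}_{i:04d}.{ 'tif' if fmt == 'tiff' else 'png'}"
        lengths = [t.length_um for t in section.incisures]
        rows.append(
            {
                "image": name,
                "disc_id": i,
                "seed": int(s),
                "diameter_um": spec.diameter,
                "rendered_diameter_um": round(section.rendered_diameter_um, 6),
                "pixel_size_nm": spec.pixel_size,
                "n_incisures": len(section.incisures),
                "incisure_lengths_um": ";".join(f"{v:.6f}" for v in lengths),
                "incisure_fractions": ";".join(
                    f"{v / spec.diameter:.6f}" for v in lengths
                ),
            }
        )
    truth = pd.DataFrame(rows)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for section, row in zip(sections, truth.itertuples()):
            path = outdir / row.image
            if fmt == "tiff":
                tifffile.imwrite(path, section.image)
            else:
                Image.fromarray(section.image).save(path)
        truth.to_csv(outdir / "ground_truth.csv", index=False)
    return sections, truth


# --------------------------------------------------------------------------
# Ratio replicates


@dataclass(frozen=True)
class RatioSampleSpec:
    """Synthetic replicate draws for the ratio table (per-genotype mean/sd)."""

    genotypes: dict  # genotype -> {ratio name -> (mean, sd)}
    replicates: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.replicates < 1:
            raise InvalidInputError(
                f"replicates must be >= 1, got {self.replicates}"
            )
        for g, entries in self.genotypes.items():
            for name, (mean, sd) in entries.items():
                if mean <= 0:
                    raise InvalidInputError(f"{g}/{name}: mean must be > 0")
                if sd < 0:
                    raise InvalidInputError(f"{g}/{name}: sd must be >= 0")


def sample_ratio_replicates(spec: RatioSampleSpec) -> pd.DataFrame:
    """Draw replicate ratio measurements from truncated normals.

    Returns a long table (genotype, quantity, replicate, value) emulating
    per-preparation measurements behind a mean +/- s.d. summary.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for genotype, entries in spec.genotypes.items():
        for name, (mean, sd) in entries.items():
            if sd == 0:
                values = np.full(spec.replicates, mean)
            else:
                a = (0.0 - mean) / sd
                values = stats.truncnorm.rvs(
                    a, np.inf, loc=mean, scale=sd, size=spec.replicates,
                    random_state=rng,
                )
            for r, v in enumerate(values, start=1):
                rows.append(
                    {
                        "genotype": genotype,
                        "quantity": name,
                        "replicate": r,
                        "value": float(v),
                    }
                )
    return pd.DataFrame(rows)
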
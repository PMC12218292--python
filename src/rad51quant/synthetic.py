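"""Synthetic data with known ground truth for the imaging and NMR pipelines.

The image generator emulates cropped yeast-nucleus stacks from wide-field
GFP microscopy: a diffuse nuclear background, zero or more curvilinear
filaments rendered as Gaussian-cross-section tubes along smooth backbones,
and/or diffraction-limited foci, convolved with a Gaussian PSF and
corrupted by Poisson shot noise plus Gaussian read noise (the standard
sCMOS model).  Strain designs control the category mixture, intensity
scales and per-batch illumination factors, so downstream detection,
classification and statistics can be scored against a recoverable answer.

The NMR generator plants a contiguous attenuated segment in a titration
peak-table pair, mirroring the intensity loss of residues in intermediate
exchange upon partner binding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import ImageStack3D
from .nmr import PeakTable, RandomCoilModel

__all__ = [
    "AcquisitionParams",
    "StrainDesign",
    "FilamentTruth",
    "FocusTruth",
    "GroundTruth",
    "render_cell",
    "simulate_experiment",
    "simulate_cell_records",
    "simulate_nmr_titration",
    "default_strain_designs",
    "synthetic_rad52_cterm_sequence",
    "write_experiment",
]

ARCHETYPES = ("simple", "complex", "foci_only", "nothing")

# physical tube cross-section: FWHM 2 px before PSF blur (130 nm at 65 nm/px)
TUBE_FWHM_PX = 2.0
_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass
class AcquisitionParams:
    """Acquisition geometry and camera model of the emulated microscope.

    Defaults follow a 100x/1.4NA wide-field system with a 6.5 um camera
    pixel (65 nm effective pixel) and a 200 nm z-step.  The denoised
    channel emulates deconvolution by rendering with a PSF narrowed by
    ``denoised_psf_factor``; it receives an independent noise realization.
    """

    pixel_nm: float = 65.0
    z_step_nm: float = 200.0
    crop_px: int = 50
    n_slices: int = 11
    psf_sigma_xy_px: float = 1.2
    psf_sigma_z_slices: float = 1.5
    denoised_psf_factor: float = 0.5
    background_level: float = 100.0
    read_noise_sd: float = 2.0
    poisson: bool = True

    def __post_init__(self) -> None:
        if self.pixel_nm <= 0 or self.z_step_nm <= 0:
            raise ValueError("physical lengths must be positive")
        if self.crop_px < 16:
            raise ValueError("crop_px must be >= 16")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if self.psf_sigma_xy_px < 0 or self.psf_sigma_z_slices < 0:
            raise ValueError("PSF sigmas must be >= 0")
        if self.background_level < 0 or self.read_noise_sd < 0:
            raise ValueError("noise levels must be >= 0")

    @property
    def width_nm_per_2px(self) -> float:
        """Physical width of the 2-pixel filament width parameter."""
        return 2.0 * self.pixel_nm


@dataclass
class StrainDesign:
    """Generative description of one strain.

    ``category_probs`` gives the archetype mixture over
    (simple, complex, foci_only, nothing).  Length is in pixels and photon
    counts are pre-noise integrated photons per structure.  The per-batch
    ``batch_intensity_factor`` multiplies all photon counts (illumination
    drift affects intensity, not geometry).
    """

    name: str
    category_probs: dict
    filament_length_px: tuple = (12.0, 4.0, 5.0, 25.0)  # mean, sd, lo, hi
    filament_photons: tuple = (50_000.0, 10_000.0)      # mean, sd
    foci_count_mean: float = 1.5
    focus_photons: tuple = (10_000.0, 3_000.0)          # mean, sd
    batch_intensity_factor: tuple = (1.0,)
    max_bow_frac: float = 0.12   # Bezier bow as a fraction of length; 0 = straight

    def __post_init__(self) -> None:
        probs = {k: float(self.category_probs.get(k, 0.0)) for k in ARCHETYPES}
        extra = set(self.category_probs) - set(ARCHETYPES)
        if extra:
            raise ValueError(f"unknown archetypes {sorted(extra)}")
        if abs(sum(probs.values()) - 1.0) > 1e-9:
            raise ValueError(f"category_probs of {self.name!r} must sum to 1")
        if any(p < 0 for p in probs.values()):
            raise ValueError("category probabilities must be >= 0")
        if self.filament_photons[0] < 0 or self.focus_photons[0] < 0:
            raise ValueError("photon means must be >= 0")
        self.category_probs = probs

    def prob_vector(self) -> np.ndarray:
        return np.array([self.category_probs[a] for a in ARCHETYPES])


@dataclass
class FilamentTruth:
    polyline_px: np.ndarray      # (N, 2) backbone points, (y, x) in pixels
    length_px: float             # true path length of the (possibly clipped) backbone
    length_nm: float
    planted_photons: float       # photons assigned before any clipping
    realized_photons: float      # post-PSF photons actually inside the crop


@dataclass
class FocusTruth:
    center_px: tuple             # (z, y, x) in pixel/slice units
    planted_photons: float
    realized_photons: float


@dataclass
class GroundTruth:
    """Per-cell truth record; `nothing` cells carry no structures."""

    archetype: str
    filaments: list = field(default_factory=list)
    foci: list = field(default_factory=list)
    background_level: float = 0.0

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.archetype!r}")
        if self.archetype == "nothing" and (self.filaments or self.foci):
            raise ValueError("a 'nothing' cell cannot carry structures")

    @property
    def total_filament_photons(self) -> float:
        return float(sum(f.planted_photons for f in self.filaments))

    @property
    def brightest_focus_photons(self) -> float:
        return float(max((f.planted_photons for f in self.foci), default=np.nan))

    @property
    def total_length_px(self) -> float:
        return float(sum(f.length_px for f in self.filaments))


# ---------------------------------------------------------------------------
# rendering primitives
# ---------------------------------------------------------------------------


def _draw_positive(rng: np.random.Generator, mean: float, sd: float,
                   lo: float = 0.0, hi: float = np.inf) -> float:
    """Normal draw resampled until it falls in (lo, hi]; negative draws are
    resampled rather than clipped so the mean is not distorted at high CV."""
    for _ in range(1000):
        value = rng.normal(mean, sd)
        if lo < value <= hi:
            return float(value)
    return float(min(max(mean, lo + 1e-9), hi))


def _bezier_polyline(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray,
                     n: int = 200) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)[:, None]
    return (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t**2 * p2


def _polyline_length(poly: np.ndarray) -> float:
    return float(np.sqrt(((np.diff(poly, axis=0)) ** 2).sum(axis=1)).sum())


def _clip_polyline(poly: np.ndarray, crop_px: int, margin: float = 1.0) -> np.ndarray:
    """Keep the longest contiguous stretch of backbone points inside the crop.

    A backbone leaving the crop is clipped (the truth length is updated by
    the caller); it is not an error.
    """
    lo, hi = margin, crop_px - 1 - margin
    inside = np.all((poly >= lo) & (poly <= hi), axis=1)
    if inside.all():
        return poly
    best_start, best_len, start = 0, 0, None
    for i, ok in enumerate(inside):
        if ok and start is None:
            start = i
        if (not ok or i == len(inside) - 1) and start is not None:
            end = i + 1 if ok else i
            if end - start > best_len:
                best_start, best_len = start, end - start
            start = None
    if best_len < 2:
        return poly[:0]
    return poly[best_start: best_start + best_len]


def _splat_points(volume: np.ndarray, points_yx: np.ndarray, weights: np.ndarray,
                  z_center: float, sigma_xy: float, sigma_z: float) -> None:
    """Deposit normalized 3D Gaussians at sub-pixel (y, x) points.

    Each splat kernel is discretely normalized over its full support before
    edge-trimming, so photons lost at the crop boundary show up as clipping
    losses rather than renormalization artifacts.
    """
    nz, ny, nx = volume.shape
    rxy = max(2, int(math.ceil(4 * sigma_xy)))
    rz = max(1, int(math.ceil(4 * sigma_z)))
    zz = np.arange(nz)
    zprof_full = np.exp(-0.5 * ((np.arange(-rz, rz + 1)) / max(sigma_z, 1e-6)) ** 2)
    offsets = np.arange(-rxy, rxy + 1)
    for (y, x), w in zip(points_yx, weights):
        iy, ix = int(round(y)), int(round(x))
        gy = np.exp(-0.5 * ((iy + offsets - y) / max(sigma_xy, 1e-6)) ** 2)
        gx = np.exp(-0.5 * ((ix + offsets - x) / max(sigma_xy, 1e-6)) ** 2)
        iz = int(round(z_center))
        gz = np.exp(-0.5 * ((iz + np.arange(-rz, rz + 1) - z_center) / max(sigma_z, 1e-6)) ** 2)
        kernel = gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
        kernel *= w / kernel.sum()
        z0, z1 = iz - rz, iz + rz + 1
        y0, y1 = iy - rxy, iy + rxy + 1
        x0, x1 = ix - rxy, ix + rxy + 1
        kz0, ky0, kx0 = max(0, -z0), max(0, -y0), max(0, -x0)
        kz1 = kernel.shape[0] - max(0, z1 - nz)
        ky1 = kernel.shape[1] - max(0, y1 - ny)
        kx1 = kernel.shape[2] - max(0, x1 - nx)
        if kz1 <= kz0 or ky1 <= ky0 or kx1 <= kx0:
            continue
        volume[max(0, z0):min(nz, z1), max(0, y0):min(ny, y1), max(0, x0):min(nx, x1)] += \
            kernel[kz0:kz1, ky0:ky1, kx0:kx1]


def _render_tube(shape: tuple, polyline: np.ndarray, z_center: float,
                 photons: float) -> np.ndarray:
    """Pre-PSF tube: Gaussian cross-section (FWHM 2 px) along the backbone."""
    volume = np.zeros(shape)
    if len(polyline) < 2 or photons <= 0:
        return volume
    seg = np.sqrt((np.diff(polyline, axis=0) ** 2).sum(axis=1))
    length = seg.sum()
    if length <= 0:
        return volume
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    n_samples = max(4, int(math.ceil(length / 0.2)))
    s = np.linspace(0.0, length, n_samples)
    ys = np.interp(s, arc, polyline[:, 0])
    xs = np.interp(s, arc, polyline[:, 1])
    weights = np.full(n_samples, photons / n_samples)
    sigma_xy = TUBE_FWHM_PX * _FWHM_TO_SIGMA
    _splat_points(volume, np.column_stack([ys, xs]), weights, z_center,
                  sigma_xy=sigma_xy, sigma_z=0.3)
    return volume


def _render_focus(shape: tuple, center_zyx: tuple, photons: float) -> np.ndarray:
    """Pre-PSF focus: a near-point emitter (sub-pixel Gaussian)."""
    volume = np.zeros(shape)
    z, y, x = center_zyx
    _splat_points(volume, np.array([[y, x]]), np.array([photons]), z,
                  sigma_xy=0.25, sigma_z=0.25)
    return volume


def _blur(volume: np.ndarray, acq: AcquisitionParams, factor: float = 1.0) -> np.ndarray:
    sigma = (acq.psf_sigma_z_slices * factor,
             acq.psf_sigma_xy_px * factor,
             acq.psf_sigma_xy_px * factor)
    return ndimage.gaussian_filter(volume, sigma=sigma, mode="constant")


def _apply_noise(expected: np.ndarray, acq: AcquisitionParams,
                 rng: np.random.Generator) -> np.ndarray:
    image = expected
    if acq.poisson:
        image = rng.poisson(np.clip(expected, 0.0, None)).astype(float)
    if acq.read_noise_sd > 0:
        image = image + rng.normal(0.0, acq.read_noise_sd, size=expected.shape)
    return image


# ---------------------------------------------------------------------------
# cell rendering
# ---------------------------------------------------------------------------


def _sample_backbone(rng: np.random.Generator, length: float, crop_px: int,
                     center_jitter: float = 5.0,
                     center: np.ndarray | None = None,
                     theta: float | None = None,
                     max_bow_frac: float = 0.12) -> np.ndarray:
    """Quadratic Bezier backbone with bounded curvature (no self-crossing)."""
    if center is None:
        center = (crop_px - 1) / 2 + rng.uniform(-center_jitter, center_jitter, size=2)
    if theta is None:
        theta = rng.uniform(0.0, np.pi)
    direction = np.array([math.sin(theta), math.cos(theta)])
    normal = np.array([-direction[1], direction[0]])
    p0 = center - direction * length / 2
    p2 = center + direction * length / 2
    bow = rng.uniform(-max_bow_frac, max_bow_frac) * length if max_bow_frac > 0 else 0.0
    p1 = center + normal * bow
    return _bezier_polyline(p0, p1, p2)


def render_cell(
    design: StrainDesign,
    archetype: str,
    acq: AcquisitionParams,
    rng_seed,
    batch: int = 0,
) -> tuple[ImageStack3D, GroundTruth]:
    """Render one nucleus crop of the given archetype.

    The noise-free intermediate is (uniform nuclear background) + (PSF-blurred
    tubes and/or foci); noise is applied last, independently for the raw and
    the denoised channel.  The ground truth records the planted photons and
    the post-PSF photons realized inside the crop (their difference is the
    clipping loss at the crop boundary).

    ``rng_seed`` may be an int or a ``numpy.random.SeedSequence``.
    """
    if archetype not in ARCHETYPES:
        raise ValueError(f"unknown archetype {archetype!r}")
    rng = np.random.default_rng(rng_seed)
    shape = (acq.n_slices, acq.crop_px, acq.crop_px)
    scale = design.batch_intensity_factor[batch] if batch < len(design.batch_intensity_factor) else 1.0
    z_mid = (acq.n_slices - 1) / 2

    filaments: list[FilamentTruth] = []
    foci: list[FocusTruth] = []
    structure_raw = np.zeros(shape)
    structure_dn = np.zeros(shape)

    def add_filament(length_scale: float = 1.0,
                     center: np.ndarray | None = None,
                     theta: float | None = None,
                     lo_min: float = 2.0) -> None:
        mean, sd, lo, hi = design.filament_length_px
        length = _draw_positive(rng, mean * length_scale, sd * length_scale,
                                lo=max(lo_min, lo * length_scale), hi=hi)
        # labeling density (photons per unit length) is the stable quantity
        # of a protein-coated filament: total photons scale with length
        photons = scale * _draw_positive(rng, *design.filament_photons) * (length / mean)
        poly = _sample_backbone(rng, length, acq.crop_px, center=center, theta=theta,
                                max_bow_frac=design.max_bow_frac)
        poly = _clip_polyline(poly, acq.crop_px)
        z_c = z_mid + rng.uniform(-0.5, 0.5)
        tube = _render_tube(shape, poly, z_c, photons)
        blurred = _blur(tube, acq)
        structure_raw[:] += blurred
        structure_dn[:] += _blur(tube, acq, factor=acq.denoised_psf_factor)
        true_len = _polyline_length(poly)
        filaments.append(FilamentTruth(
            polyline_px=poly, length_px=true_len,
            length_nm=true_len * acq.pixel_nm,
            planted_photons=photons,
            realized_photons=float(blurred.sum()),
        ))

    def add_focus() -> None:
        # rejection-sample centers at least 6 px apart: closer spots are not
        # resolvable as distinct foci at this PSF
        margin = 8.0
        center = None
        for _ in range(50):
            cand = (
                z_mid + rng.uniform(-1.5, 1.5),
                rng.uniform(margin, acq.crop_px - 1 - margin),
                rng.uniform(margin, acq.crop_px - 1 - margin),
            )
            if all((cand[1] - f.center_px[1]) ** 2 + (cand[2] - f.center_px[2]) ** 2 >= 36.0
                   for f in foci):
                center = cand
                break
        if center is None:
            return
        photons = scale * _draw_positive(rng, *design.focus_photons)
        spot = _render_focus(shape, center, photons)
        blurred = _blur(spot, acq)
        structure_raw[:] += blurred
        structure_dn[:] += _blur(spot, acq, factor=acq.denoised_psf_factor)
        foci.append(FocusTruth(center_px=center, planted_photons=photons,
                               realized_photons=float(blurred.sum())))

    if archetype == "simple":
        add_filament()
    elif archetype == "complex":
        # two filaments crossing at a clear angle, giving a branched or
        # multi-component skeleton; both branches are resolvable filaments
        # (>= 8 px), since a shorter stub over a filament is not visually a
        # distinct structure
        add_filament(lo_min=8.0)
        first = filaments[0].polyline_px
        if len(first) >= 2:
            t = rng.uniform(0.3, 0.7)
            anchor = first[int(t * (len(first) - 1))]
            d0 = first[-1] - first[0]
            theta0 = math.atan2(d0[0], d0[1])
            theta2 = theta0 + rng.choice([-1, 1]) * rng.uniform(math.pi / 4, math.pi / 2)
            add_filament(center=np.array(anchor, dtype=float), theta=theta2,
                         lo_min=8.0)
        else:
            add_filament(lo_min=8.0)
    elif archetype == "foci_only":
        n_foci = max(1, int(rng.poisson(design.foci_count_mean)))
        for _ in range(n_foci):
            add_focus()

    background = np.full(shape, float(acq.background_level))
    raw = _apply_noise(background + structure_raw, acq, rng)
    denoised = _apply_noise(background + structure_dn, acq, rng)

    stack = ImageStack3D(data=raw, pixel_nm=acq.pixel_nm, z_step_nm=acq.z_step_nm,
                         denoised=denoised)
    truth = GroundTruth(archetype=archetype, filaments=filaments, foci=foci,
                        background_level=float(acq.background_level))
    return stack, truth


# ---------------------------------------------------------------------------
# experiment-level simulation
# ---------------------------------------------------------------------------


def default_strain_designs(n_batches: int = 3) -> list[StrainDesign]:
    """Study-like default designs for a four-strain experiment.

    The mixture emulates the published phenotype pattern: wild-type cells
    mostly form filaments or bright foci; filament-assembly mutants mostly
    show foci 5-10 fold dimmer than wild type, with no detectable structure
    in a substantial fraction of cells; an srs2-null background forms
    slightly more filaments than wild type.  Batch factors model
    session-to-session illumination drift.
    """
    factors = tuple(1.0 + 0.15 * math.sin(2.0 * math.pi * b / max(n_batches, 1))
                    for b in range(n_batches))
    return [
        StrainDesign(
            name="WT",
            category_probs={"simple": 0.55, "complex": 0.25, "foci_only": 0.15, "nothing": 0.05},
            batch_intensity_factor=factors,
        ),
        StrainDesign(
            name="srs2D",
            category_probs={"simple": 0.60, "complex": 0.25, "foci_only": 0.10, "nothing": 0.05},
            filament_photons=(60_000.0, 12_000.0),
            batch_intensity_factor=factors,
        ),
        StrainDesign(
            name="rad52-F316A",
            category_probs={"simple": 0.03, "complex": 0.02, "foci_only": 0.61, "nothing": 0.34},
            filament_photons=(15_000.0, 5_000.0),
            focus_photons=(1_500.0, 500.0),
            batch_intensity_factor=factors,
        ),
        StrainDesign(
            name="rad52-Y376A",
            category_probs={"simple": 0.10, "complex": 0.05, "foci_only": 0.65, "nothing": 0.20},
            filament_photons=(25_000.0, 8_000.0),
            focus_photons=(2_500.0, 800.0),
            batch_intensity_factor=factors,
        ),
    ]


def simulate_experiment(
    designs: list,
    n_cells: int,
    n_batches: int,
    acq: AcquisitionParams | None = None,
    seed: int = 0,
) -> tuple[list, pd.DataFrame]:
    """Render ``n_cells`` crops per strain, batches assigned round-robin.

    Returns ``(cells, truth_table)`` where ``cells`` is a list of
    ``(ImageStack3D, meta)`` pairs — ``meta`` holds cell_id, strain, batch
    and the full :class:`GroundTruth` — and ``truth_table`` is its tabular
    summary.  Identical (designs, seed) give a bit-identical dataset: every
    cell draws from its own child stream of a single seed sequence.
    """
    acq = acq if acq is not None else AcquisitionParams()
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    names = [d.name for d in designs]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate strain names in designs: {names}")
    for d in designs:
        if len(d.batch_intensity_factor) < n_batches:
            raise ValueError(
                f"design {d.name!r} provides {len(d.batch_intensity_factor)} batch "
                f"factors but n_batches={n_batches}")

    children = np.random.SeedSequence(seed).spawn(len(designs) * n_cells)
    cells = []
    rows = []
    idx = 0
    for design in designs:
        for i in range(n_cells):
            child = children[idx]
            idx += 1
            batch = i % n_batches
            rng = np.random.default_rng(child)
            archetype = ARCHETYPES[rng.choice(len(ARCHETYPES), p=design.prob_vector())]
            stack, truth = render_cell(design, archetype, acq,
                                       rng_seed=rng, batch=batch)
            cell_id = f"{design.name}_{i:04d}"
            meta = {"cell_id": cell_id, "strain": design.name,
                    "batch": f"b{batch}", "truth": truth}
            cells.append((stack, meta))
            rows.append({
                "cell_id": cell_id,
                "strain": design.name,
                "batch": f"b{batch}",
                "archetype": archetype,
                "n_filaments": len(truth.filaments),
                "total_length_px": truth.total_length_px,
                "filament_photons": truth.total_filament_photons,
                "n_foci": len(truth.foci),
                "brightest_focus_photons": truth.brightest_focus_photons,
            })
    return cells, pd.DataFrame(rows)


def simulate_cell_records(
    designs: list,
    n_cells: int,
    n_batches: int = 1,
    seed: int = 0,
    measurement_cv: float = 0.05,
) -> pd.DataFrame:
    """Draw per-cell feature records directly, without rendering images.

    This samples from the same strain designs as the image generator
    (category mixture, intensity and length distributions, batch factors)
    plus a multiplicative measurement error, and is the fast input for
    statistical calibration studies (type-I error, FDR control) where the
    imaging stage itself is not under test.
    """
    names = [d.name for d in designs]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate strain names in designs: {names}")
    rng = np.random.default_rng(seed)
    rows = []
    for design in designs:
        for i in range(n_cells):
            batch = i % n_batches
            scale = design.batch_intensity_factor[batch] \
                if batch < len(design.batch_intensity_factor) else 1.0
            archetype = ARCHETYPES[rng.choice(len(ARCHETYPES), p=design.prob_vector())]
            noise = lambda: rng.normal(1.0, measurement_cv)
            row = {
                "cell_id": f"{design.name}_{i:04d}",
                "strain": design.name,
                "batch": f"b{batch}",
                "category": None,
                "hasFilament": 0,
                "filamentLength": np.nan,
                "filamentIntensity": np.nan,
                "spotIntensity": np.nan,
            }
            if archetype == "simple":
                mean, sd, lo, hi = design.filament_length_px
                row.update(category="Simple", hasFilament=1,
                           filamentLength=_draw_positive(rng, mean, sd, lo=lo, hi=hi),
                           filamentIntensity=scale * _draw_positive(rng, *design.filament_photons) * noise())
            elif archetype == "complex":
                row.update(category="Complex", hasFilament=1)
            elif archetype == "foci_only":
                n_foci = max(1, int(rng.poisson(design.foci_count_mean)))
                draws = [scale * _draw_positive(rng, *design.focus_photons) * noise()
                         for _ in range(n_foci)]
                row.update(category="Foci", spotIntensity=max(draws))
            else:
                row.update(category="Nothing")
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# NMR titration simulation
# ---------------------------------------------------------------------------

# Amino-acid frequencies biased toward disorder-promoting residues, used to
# draw the synthetic disordered-tail sequence.
_DISORDER_AA = "ACDEFGHIKLMNPQRSTVWY"
_DISORDER_FREQ = np.array([
    0.06, 0.01, 0.07, 0.09, 0.03, 0.07, 0.02, 0.03, 0.08, 0.05,
    0.02, 0.07, 0.06, 0.07, 0.04, 0.11, 0.06, 0.04, 0.01, 0.01,
])


def synthetic_rad52_cterm_sequence(start_residue: int = 206,
                                   end_residue: int = 471) -> str:
    """A fixed synthetic stand-in for a disordered C-terminal tail.

    Deterministically generated with disorder-biased residue frequencies.
    Prolines are kept away from residues 309-311 and 394-396 so that the
    canonical planted interaction boundaries (310 and 395) carry observable
    amides.  This is a synthetic sequence, not the real Rad52 sequence.
    """
    rng = np.random.default_rng(np.random.SeedSequence(20240052))
    freq = _DISORDER_FREQ / _DISORDER_FREQ.sum()
    n = end_residue - start_residue + 1
    letters = [ _DISORDER_AA[i] for i in rng.choice(len(_DISORDER_AA), size=n, p=freq) ]
    guarded = set(range(309, 312)) | set(range(394, 397))
    no_pro = _DISORDER_AA.replace("P", "")
    freq_np = np.delete(freq, _DISORDER_AA.index("P"))
    freq_np = freq_np / freq_np.sum()
    for res in guarded:
        i = res - start_residue
        if 0 <= i < n and letters[i] == "P":
            letters[i] = no_pro[rng.choice(len(no_pro), p=freq_np)]
    return "".join(letters)


def simulate_nmr_titration(
    sequence: str,
    region: tuple,
    attenuation: float,
    noise_cv: float = 0.0,
    seed: int = 0,
    start_residue: int = 1,
    ca_deviations: dict | None = None,
    rc: RandomCoilModel | None = None,
) -> tuple[PeakTable, PeakTable]:
    """Simulate a (free, bound) peak-table pair with a planted binding region.

    Bound intensities equal the free intensity times ``attenuation`` inside
    ``region`` (inclusive residue interval) and are unchanged outside, then
    receive multiplicative Gaussian noise with coefficient of variation
    ``noise_cv``.  Prolines are absent from both tables.  Observed C-alpha
    shifts equal the random-coil prediction plus optional planted
    deviations (``ca_deviations``: residue -> ppm), so the chemical shift
    index of an unperturbed residue is exactly zero.
    """
    if not sequence:
        raise ValueError("empty sequence")
    if not (0.0 <= attenuation <= 1.0):
        raise ValueError("attenuation must lie in [0, 1]")
    lo, hi = int(region[0]), int(region[1])
    end_residue = start_residue + len(sequence) - 1
    if lo > hi or lo < start_residue or hi > end_residue:
        raise ValueError(
            f"region [{lo}, {hi}] outside sequence numbering [{start_residue}, {end_residue}]")
    rng = np.random.default_rng(seed)
    rc = rc if rc is not None else RandomCoilModel()
    coil = rc.predict(sequence, start_residue=start_residue)
    ca_deviations = ca_deviations or {}

    rows_free, rows_bound = [], []
    for i, aa in enumerate(sequence):
        if aa == "P":
            continue  # no backbone amide
        res = start_residue + i
        base = rng.uniform(0.8, 1.2)
        ca = coil.loc[res] + float(ca_deviations.get(res, 0.0))
        factor = attenuation if lo <= res <= hi else 1.0
        bound_int = base * factor
        if noise_cv > 0:
            bound_int *= max(rng.normal(1.0, noise_cv), 1e-6)
        rows_free.append({"residue": res, "aa": aa, "intensity": base, "ca_shift": ca})
        rows_bound.append({"residue": res, "aa": aa, "intensity": bound_int, "ca_shift": ca})
    return PeakTable(pd.DataFrame(rows_free)), PeakTable(pd.DataFrame(rows_bound))


# ---------------------------------------------------------------------------
# on-disk dataset
# ---------------------------------------------------------------------------


def write_experiment(outdir, cells: list, truth_table: pd.DataFrame) -> pd.DataFrame:
    """Write a simulated dataset: one multi-page TIFF per cell (one page per
    z-slice), a sibling ``*_dn.tif`` for the denoised channel, plus
    ``metadata.csv`` and ``ground_truth.csv``.  Returns the metadata table.
    """
    import tifffile
    from pathlib import Path

    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    meta_rows = []
    for stack, meta in cells:
        fname = f"{meta['cell_id']}.tif"
        tifffile.imwrite(outdir / "images" / fname, stack.data.astype(np.float32))
        dn_name = ""
        if stack.denoised is not None:
            dn_name = f"{meta['cell_id']}_dn.tif"
            tifffile.imwrite(outdir / "images" / dn_name, stack.denoised.astype(np.float32))
        meta_rows.append({"cell_id": meta["cell_id"], "strain": meta["strain"],
                          "batch": meta["batch"], "file": fname, "denoised_file": dn_name})
    metadata = pd.DataFrame(meta_rows)
    metadata.to_csv(outdir / "metadata.csv", index=False)
    truth_table.to_csv(outdir / "ground_truth.csv", index=False)
    return metadata
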
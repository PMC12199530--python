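"""Seeded phantom generators with exact ground truth.

Three phantom families mirror the three imaging assays the package analyzes:

* **Section phantoms** — kidney cross-sections with disk-like glomeruli. The
  marker channel (e.g. synaptopodin) defines the ROIs; the target channel
  (e.g. MAGI2) carries a group-level multiplicative intensity effect with
  log-normal per-glomerulus noise.
* **Slit phantoms** — super-resolution-like two-channel images of the podocyte
  filtration slit. Healthy slits are dense meandering curves on the capillary;
  effacement linearizes and thins them. Ground truth records the analytic
  curve length and the capillary ellipse area, hence an exact filtration slit
  density (FSD).
* **Vessel movies** — short brightfield movies of the larval tail vasculature:
  a static textured background with dark erythrocyte-like specks translating
  only inside the vessel band, paired with one fluorescence frame whose
  intravascular level encodes circulating gc-eGFP.

All generators are driven by a single integer seed and are bit-reproducible.
Packaged fixture tables (patient characteristics and study group sizes) are
exposed through :func:`load_fixture_tables`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .core import GroundTruth, ImageStack, LabelMask

logger = logging.getLogger(__name__)

__all__ = [
    "SectionPhantomSpec",
    "SlitPhantomSpec",
    "VesselBand",
    "MoviePhantomSpec",
    "PlacementError",
    "gen_section_phantom",
    "gen_slit_phantom",
    "gen_vessel_movie",
    "gen_section_cohort",
    "gen_larva_cohort",
    "load_fixture_tables",
    "polyline_length",
]


class PlacementError(RuntimeError):
    """Raised when non-overlapping glomeruli cannot be placed in the image."""


# ---------------------------------------------------------------------------
# Section phantoms (glomeruli in tissue cross-sections)
# ---------------------------------------------------------------------------

@dataclass
class SectionPhantomSpec:
    """Parameters of a kidney-section phantom for one subject.

    The default pixel size (2.64 px/µm) matches confocal imaging of human
    glomeruli; the target-channel mean inside glomerulus *g* is
    ``subject_base * group_effects[group]`` corrupted by multiplicative
    log-normal noise with coefficient of variation ``noise_cv``.
    """

    image_size_px: tuple[int, int] = (1200, 1200)
    pixels_per_micron: float = 2.64
    n_glomeruli: int = 20
    glomerulus_radius_um: tuple[float, float] = (18.0, 26.0)
    group_effects: dict[str, float] = field(
        default_factory=lambda: {"control": 1.0, "MCD": 1.3, "Prim FSGS": 0.6, "Sec FSGS": 1.0}
    )
    group: str = "control"
    subject_base: float = 100.0
    noise_cv: float = 0.2
    background_level: float = 10.0
    marker_level: float = 200.0
    min_gap_um: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.pixels_per_micron > 0:
            raise ValueError("pixels_per_micron must be positive")
        if any(f <= 0 for f in self.group_effects.values()):
            raise ValueError("group effect factors must be positive")
        if self.group not in self.group_effects:
            raise ValueError(f"group {self.group!r} not in group_effects")
        lo, hi = self.glomerulus_radius_um
        if not (0 < lo <= hi):
            raise ValueError("glomerulus_radius_um must be an increasing positive range")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.n_glomeruli < 0:
            raise ValueError("n_glomeruli must be >= 0")


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative noise with mean exactly 1 and coefficient of variation cv."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma = np.sqrt(np.log1p(cv**2))
    return np.exp(rng.normal(-0.5 * sigma**2, sigma, size=size))


def _place_disks(rng, shape, radii_px, gap_px, max_attempts):
    centers: list[tuple[float, float]] = []
    placed_r: list[float] = []
    attempts = 0
    for r in radii_px:
        while True:
            attempts += 1
            if attempts > max_attempts:
                raise PlacementError(
                    f"could not place {len(radii_px)} non-overlapping glomeruli "
                    f"in a {shape[0]}x{shape[1]} image after {max_attempts} attempts"
                )
            cy = rng.uniform(r, shape[0] - r)
            cx = rng.uniform(r, shape[1] - r)
            ok = all(
                (cy - y0) ** 2 + (cx - x0) ** 2 >= (r + r0 + gap_px) ** 2
                for (y0, x0), r0 in zip(centers, placed_r)
            )
            if ok:
                centers.append((cy, cx))
                placed_r.append(r)
                break
    return centers


def gen_section_phantom(spec: SectionPhantomSpec) -> tuple[ImageStack, GroundTruth]:
    """Render one two-channel section phantom and its exact ground truth.

    Returns an :class:`ImageStack` with channels ``("marker", "target")`` and a
    :class:`GroundTruth` holding the label mask and the exact per-label mean of
    the rendered target channel.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size_px
    ppm = spec.pixels_per_micron

    marker = np.full((h, w), spec.background_level, dtype=np.float64)
    target = np.full((h, w), spec.background_level, dtype=np.float64)
    labels = np.zeros((h, w), dtype=np.int32)

    if spec.n_glomeruli > 0:
        lo, hi = spec.glomerulus_radius_um
        radii_px = rng.uniform(lo, hi, spec.n_glomeruli) * ppm
        gap_px = spec.min_gap_um * ppm
        centers = _place_disks(
            rng, (h, w), radii_px, gap_px, max_attempts=400 * spec.n_glomeruli
        )
        factor = spec.group_effects[spec.group]
        for lab, ((cy, cx), r) in enumerate(zip(centers, radii_px), start=1):
            y0, y1 = max(0, int(np.floor(cy - r))), min(h, int(np.ceil(cy + r)) + 1)
            x0, x1 = max(0, int(np.floor(cx - r))), min(w, int(np.ceil(cx + r)) + 1)
            yy, xx = np.mgrid[y0:y1, x0:x1]
            inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
            # textured interior so the marker channel is not piecewise constant
            tex = np.clip(rng.normal(1.0, 0.15, inside.shape), 0.3, None)
            patch_m = marker[y0:y1, x0:x1]
            patch_m[inside] = spec.marker_level * tex[inside]
            v = spec.subject_base * factor * _lognormal_factor(rng, spec.noise_cv)
            patch_t = target[y0:y1, x0:x1]
            patch_t[inside] = v
            labels[y0:y1, x0:x1][inside] = lab

    stack = ImageStack(
        np.stack([marker, target]), ["marker", "target"], ppm
    )
    true_means = {
        int(lab): float(target[labels == lab].mean())
        for lab in np.unique(labels[labels > 0])
    }
    gt = GroundTruth(
        label_mask=LabelMask(labels, provenance="phantom"), true_roi_means=true_means
    )
    return stack, gt


def gen_section_cohort(
    n_subjects_per_group: int,
    base_spec: SectionPhantomSpec | None = None,
    subject_cv: float = 0.1,
    seed: int = 0,
):
    """Yield ``(subject_id, group, ImageStack, GroundTruth)`` for a full cohort.

    One image per subject; subjects inherit ``base_spec`` with a log-normal
    between-subject baseline variability of coefficient ``subject_cv`` and a
    fresh child seed.
    """
    base = base_spec or SectionPhantomSpec()
    rng = np.random.default_rng(seed)
    for group in base.group_effects:
        for i in range(n_subjects_per_group):
            sid = f"{group}-{i + 1}"
            sub_base = base.subject_base * _lognormal_factor(rng, subject_cv)
            spec = SectionPhantomSpec(
                image_size_px=base.image_size_px,
                pixels_per_micron=base.pixels_per_micron,
                n_glomeruli=base.n_glomeruli,
                glomerulus_radius_um=base.glomerulus_radius_um,
                group_effects=base.group_effects,
                group=group,
                subject_base=float(sub_base),
                noise_cv=base.noise_cv,
                background_level=base.background_level,
                marker_level=base.marker_level,
                min_gap_um=base.min_gap_um,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            stack, gt = gen_section_phantom(spec)
            yield sid, group, stack, gt


# ---------------------------------------------------------------------------
# Slit phantoms (filtration slits on a capillary, super-resolution scale)
# ---------------------------------------------------------------------------

@dataclass
class SlitPhantomSpec:
    """Parameters of a two-channel filtration-slit phantom.

    ``effacement`` interpolates between dense meandering curves (0, healthy)
    and sparse nearly straight chords (1, fully effaced). The two channels
    ("magi2", "nephrin") are rasterized from the same curve set; the second is
    scaled by ``channel_gain_ratio`` and both receive independent additive
    Gaussian noise. The ground-truth FSD at effacement 0 equals
    ``target_fsd_per_um`` exactly (curve generation is trimmed to the length
    budget).
    """

    image_size_px: tuple[int, int] = (512, 512)
    pixel_size_nm: float = 30.0
    psf_fwhm_nm: float = 119.0
    effacement: float = 0.0
    target_fsd_per_um: float = 3.0
    channel_gain_ratio: float = 1.0
    channel_noise_sd: tuple[float, float] = (0.0, 0.0)
    capillary_axes_um: tuple[float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.pixel_size_nm > 0 or not self.psf_fwhm_nm > 0:
            raise ValueError("pixel_size_nm and psf_fwhm_nm must be positive")
        if not 0.0 <= self.effacement <= 1.0:
            raise ValueError("effacement must lie in [0, 1]")
        if not self.target_fsd_per_um > 0:
            raise ValueError("target_fsd_per_um must be positive")
        if not self.channel_gain_ratio > 0:
            raise ValueError("channel_gain_ratio must be positive")


def polyline_length(points_um: np.ndarray) -> float:
    """Analytic length of a polyline (sum of segment lengths), in µm."""
    pts = np.asarray(points_um, dtype=float)
    if pts.ndim != 2 or len(pts) < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def _trim_polyline(pts: np.ndarray, target_len: float) -> np.ndarray:
    """Cut a polyline at exactly ``target_len`` arc length."""
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    if cum[-1] <= target_len:
        return pts
    i = int(np.searchsorted(cum, target_len))
    frac = (target_len - cum[i - 1]) / seg[i - 1]
    end = pts[i - 1] + frac * (pts[i] - pts[i - 1])
    return np.vstack([pts[:i], end])


def _meander_curves(rng, a, b, cy, cx, effacement, budget, step=0.15):
    """Meandering slit curves tiling an ellipse, with analytic length ≈ budget.

    Slits form locally parallel interdigitation patterns, so curves are built
    as evenly spaced chords along a random dominant orientation, displaced by
    a smooth random meander whose amplitude shrinks with effacement. The chord
    spacing is iterated so the total analytic length matches the budget, then
    curves (in shuffled order) are trimmed to the budget exactly.
    """
    from scipy.ndimage import gaussian_filter1d

    area = np.pi * a * b
    u_ang = rng.uniform(0, np.pi)  # dominant slit orientation
    u = np.array([np.sin(u_ang), np.cos(u_ang)])  # (dy, dx)
    nvec = np.array([-u[1], u[0]])
    r_max = max(a, b)
    corr_um = 0.8  # meander correlation length along the chord

    spacing = area / budget * 1.2
    curves: list[np.ndarray] = []
    for _ in range(3):
        curves = []
        amp = 0.30 * spacing * (1.0 - effacement)
        offsets = np.arange(-r_max, r_max, spacing) + rng.uniform(
            -0.15 * spacing, 0.15 * spacing
        )
        t = np.arange(-r_max, r_max, step)

        def _smooth_unit(n):
            f = gaussian_filter1d(rng.standard_normal(n), corr_um / step, mode="wrap")
            rms = np.sqrt(np.mean(f**2))
            return f / rms if rms > 0 else f

        # adjacent slits undulate together (interdigitating foot processes):
        # a shared meander field plus a smaller per-chord component keeps the
        # inter-slit gap near the foot-process width instead of collapsing
        common = _smooth_unit(t.size)
        for off in offsets:
            if amp > 0:
                d = amp * (0.9 * common + 0.436 * _smooth_unit(t.size))
            else:
                d = np.zeros(t.size)
            pts = (
                np.array([cy, cx])[None]
                + t[:, None] * u[None]
                + (off + d)[:, None] * nvec[None]
            )
            inside = ((pts[:, 0] - cy) / b) ** 2 + ((pts[:, 1] - cx) / a) ** 2 <= 1.0
            # split into contiguous in-ellipse runs
            idx = np.flatnonzero(inside)
            if idx.size < 2:
                continue
            breaks = np.flatnonzero(np.diff(idx) > 1)
            for run in np.split(idx, breaks + 1):
                if run.size >= 2:
                    curves.append(pts[run])
        total = sum(polyline_length(c) for c in curves)
        if total <= 0:
            spacing *= 0.5
            continue
        if abs(total - budget) / budget < 0.02 and total >= budget:
            break
        # total scales ~1/spacing; aim slightly above budget so trimming works
        spacing *= total / (1.01 * budget)

    rng.shuffle(curves)
    out, running = [], 0.0
    for c in curves:
        length = polyline_length(c)
        if running + length >= budget:
            c = _trim_polyline(c, budget - running)
            if len(c) >= 2:
                out.append(c)
            running = budget
            break
        out.append(c)
        running += length
    return out, running


def gen_slit_phantom(spec: SlitPhantomSpec) -> tuple[ImageStack, GroundTruth]:
    """Render a two-channel slit phantom with exact analytic ground truth.

    Curves are evenly spaced meandering chords clipped to an elliptical
    capillary region (see :func:`_meander_curves`); effacement lowers the
    length budget ``target_fsd * area * (1 - 0.75*effacement)`` and
    straightens the curves. Generation is trimmed to the budget, so the
    ground-truth length and FSD are exact by construction.
    """
    if spec.pixel_size_nm > spec.psf_fwhm_nm / 2:
        logger.warning(
            "pixel size %.1f nm undersamples a %.1f nm PSF (Nyquist %.1f nm)",
            spec.pixel_size_nm,
            spec.psf_fwhm_nm,
            spec.psf_fwhm_nm / 2,
        )
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size_px
    px_um = spec.pixel_size_nm / 1000.0  # µm per pixel
    h_um, w_um = h * px_um, w * px_um
    if spec.capillary_axes_um is not None:
        a, b = spec.capillary_axes_um[0] / 2.0, spec.capillary_axes_um[1] / 2.0
    else:
        a, b = 0.42 * w_um, 0.42 * h_um
    cy, cx = h_um / 2.0, w_um / 2.0
    area = float(np.pi * a * b)

    e = spec.effacement
    budget = spec.target_fsd_per_um * area * (1.0 - 0.75 * e)
    # slits at the capillary edge trace its outline; the rim curve is part of
    # the curve set and counts toward the analytic length budget
    t_rim = np.linspace(0.0, 2 * np.pi, max(16, int(np.pi * (a + b) / 0.1)))
    rim = np.stack([cy + 0.995 * b * np.sin(t_rim), cx + 0.995 * a * np.cos(t_rim)], axis=1)
    rim_len = polyline_length(rim)
    if rim_len < 0.6 * budget:
        curves, total = _meander_curves(rng, a, b, cy, cx, e, budget - rim_len)
        curves.append(rim)
        total += rim_len
    else:
        curves, total = _meander_curves(rng, a, b, cy, cx, e, budget)

    # rasterize: dense resampling -> binary line image -> PSF blur
    raster = np.zeros((h, w), dtype=np.float64)
    for pts in curves:
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        if cum[-1] <= 0:
            continue
        s = np.arange(0, cum[-1], 0.25 * px_um)
        ry = np.interp(s, cum, pts[:, 0]) / px_um
        rx = np.interp(s, cum, pts[:, 1]) / px_um
        iy = np.clip(np.round(ry).astype(int), 0, h - 1)
        ix = np.clip(np.round(rx).astype(int), 0, w - 1)
        raster[iy, ix] = 1.0

    sigma_px = spec.psf_fwhm_nm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / spec.pixel_size_nm
    base = gaussian_filter(raster, sigma_px)
    if base.max() > 0:
        base = base * (100.0 / base.max())

    sd1, sd2 = spec.channel_noise_sd
    magi2 = base + (rng.normal(0.0, sd1, base.shape) if sd1 > 0 else 0.0)
    nephrin = base * spec.channel_gain_ratio + (
        rng.normal(0.0, sd2, base.shape) if sd2 > 0 else 0.0
    )
    ppm = 1.0 / px_um
    stack = ImageStack(np.stack([magi2, nephrin]), ["magi2", "nephrin"], ppm)
    gt = GroundTruth(
        slit_mask=raster > 0,
        true_slit_length_um=float(total),
        true_capillary_area_um2=area,
    )
    return stack, gt


# ---------------------------------------------------------------------------
# Vessel movies (zebrafish tail vasculature, brightfield + gc-eGFP frame)
# ---------------------------------------------------------------------------

@dataclass
class VesselBand:
    """Straight vessel segment: axis endpoints in pixel coords and width in µm."""

    p0_px: tuple[float, float]
    p1_px: tuple[float, float]
    width_um: float = 15.0


@dataclass
class MoviePhantomSpec:
    """Parameters of a brightfield movie + fluorescence frame phantom.

    Defaults follow the acquisition the analysis targets: a 10-frame
    brightfield movie at 0.65 µm/px followed by one 488 nm frame. The vessel
    is a straight band; erythrocyte-like dark specks translate along its axis
    (wrapping around) and are masked so no speck intensity leaks outside the
    vessel.
    """

    n_frames: int = 10
    frame_size_px: tuple[int, int] = (128, 160)
    pixel_size_um: float = 0.65
    vessel: VesselBand | None = None
    speck_density_per_um2: float = 0.05
    speck_speed_px_per_frame: float = 4.0
    plasma_level: float = 100.0
    background_level: float = 40.0
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        if self.plasma_level < 0 or self.speck_density_per_um2 < 0:
            raise ValueError("plasma_level and speck_density must be >= 0")


def _band_mask(shape, band: VesselBand, pixel_size_um):
    h, w = shape
    p0 = np.asarray(band.p0_px, dtype=float)
    p1 = np.asarray(band.p1_px, dtype=float)
    axis = p1 - p0
    length = np.linalg.norm(axis)
    if length == 0:
        raise ValueError("vessel endpoints coincide")
    u = axis / length
    yy, xx = np.mgrid[0:h, 0:w]
    rel = np.stack([yy - p0[0], xx - p0[1]], axis=-1)
    s = rel @ u
    t = rel @ np.array([-u[1], u[0]])
    half_w = band.width_um / pixel_size_um / 2.0
    mask = (s >= 0) & (s <= length) & (np.abs(t) <= half_w)
    return mask, p0, u, float(length), half_w


def gen_vessel_movie(
    spec: MoviePhantomSpec,
) -> tuple[ImageStack, ImageStack, GroundTruth]:
    """Render a brightfield movie, an eGFP frame, and the true vessel mask.

    Returns ``(frames, egfp, truth)`` where ``frames`` is an ImageStack with
    one channel per time point.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.frame_size_px
    band = spec.vessel or VesselBand((h / 2.0, 0.0), (h / 2.0, float(w)), 15.0)
    mask, p0, u, length, half_w = _band_mask((h, w), band, spec.pixel_size_um)
    if spec.speck_speed_px_per_frame >= length:
        raise ValueError(
            f"speck speed {spec.speck_speed_px_per_frame} px/frame exceeds "
            f"vessel length {length:.1f} px"
        )

    # static textured background, identical in all frames
    background = spec.background_level * (
        1.0 + 0.25 * gaussian_filter(rng.standard_normal((h, w)), 4.0)
    )
    background = np.clip(background, 1.0, None)

    area_um2 = mask.sum() * spec.pixel_size_um**2
    n_specks = int(round(spec.speck_density_per_um2 * area_um2))
    speck_sigma = 1.5  # px
    margin = 2.0 * speck_sigma
    s0 = rng.uniform(0.0, length, n_specks)
    t0 = rng.uniform(-max(half_w - margin, 0.0), max(half_w - margin, 0.0), n_specks)
    perp = np.array([-u[1], u[0]])
    maskf = mask.astype(np.float64)

    frames = np.empty((spec.n_frames, h, w), dtype=np.float64)
    for k in range(spec.n_frames):
        speck_img = np.zeros((h, w), dtype=np.float64)
        s = (s0 + k * spec.speck_speed_px_per_frame) % length
        centers = p0[None, :] + s[:, None] * u[None, :] + t0[:, None] * perp[None, :]
        r = int(np.ceil(3 * speck_sigma))
        for cyx in centers:
            cy, cx = cyx
            y0, y1 = int(np.floor(cy)) - r, int(np.floor(cy)) + r + 1
            x0, x1 = int(np.floor(cx)) - r, int(np.floor(cx)) + r + 1
            ys, xs = max(y0, 0), max(x0, 0)
            ye, xe = min(y1, h), min(x1, w)
            if ye <= ys or xe <= xs:
                continue
            yy, xx = np.mgrid[ys:ye, xs:xe]
            blob = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * speck_sigma**2))
            speck_img[ys:ye, xs:xe] += blob
        # specks exist only in the lumen: clip the blob tails at the vessel wall
        frames[k] = np.clip(background - 0.5 * spec.background_level * np.clip(speck_img, 0, 1) * maskf, 0.5, None)

    egfp = spec.plasma_level * maskf + spec.background_level * (1.0 - maskf)
    if spec.noise_sd > 0:
        egfp = egfp + rng.normal(0.0, spec.noise_sd, egfp.shape)

    ppm = 1.0 / spec.pixel_size_um
    movie = ImageStack(frames, [f"t{k:03d}" for k in range(spec.n_frames)], ppm)
    egfp_stack = ImageStack(egfp[np.newaxis], ["egfp"], ppm)
    gt = GroundTruth(vessel_mask=mask, true_plasma_level=spec.plasma_level)
    return movie, egfp_stack, gt


def gen_larva_cohort(
    n_per_group: int = 24,
    group_plasma: dict[str, float] | None = None,
    larva_cv: float = 0.25,
    base_spec: MoviePhantomSpec | None = None,
    seed: int = 0,
):
    """Yield ``(larva_id, group, movie, egfp, truth)`` for a screening cohort.

    Per-larva plasma levels are log-normally dispersed around the group mean
    with coefficient of variation ``larva_cv`` (biological variability of
    circulating gc-eGFP between individual larvae).
    """
    base = base_spec or MoviePhantomSpec()
    plasma = group_plasma or {"uninjected": 100.0, "KO": 70.0}
    rng = np.random.default_rng(seed)
    for group, level in plasma.items():
        for i in range(n_per_group):
            lid = f"{group}-{i + 1}"
            p = float(level * _lognormal_factor(rng, larva_cv))
            spec = MoviePhantomSpec(
                n_frames=base.n_frames,
                frame_size_px=base.frame_size_px,
                pixel_size_um=base.pixel_size_um,
                vessel=base.vessel,
                speck_density_per_um2=base.speck_density_per_um2,
                speck_speed_px_per_frame=base.speck_speed_px_per_frame,
                plasma_level=p,
                background_level=base.background_level,
                noise_sd=base.noise_sd,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            movie, egfp, gt = gen_vessel_movie(spec)
            yield lid, group, movie, egfp, gt


# ---------------------------------------------------------------------------
# Packaged fixture tables
# ---------------------------------------------------------------------------

def load_fixture_tables() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Load the packaged patient-characteristics and study-design tables.

    Returns ``(patients, design)``. Proteinuria units are heterogeneous in the
    source records and are stored verbatim, never converted;
    ``proteinuria_censored`` marks values reported as lower bounds (">").
    """
    data = resources.files("podoquant") / "data"
    with (data / "patient_characteristics.csv").open() as fh:
        patients = pd.read_csv(fh, keep_default_na=False)
    patients["proteinuria_censored"] = patients["proteinuria_censored"].map(
        {True: True, False: False, "True": True, "False": False}
    ).astype(bool)
    with (data / "study_design.csv").open() as fh:
        design = pd.read_csv(fh, keep_default_na=False)
    return patients, design
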
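"""Synthetic IVUS pullback phantom generator.

Real IVUS training data are cross-sectional grayscale frames extracted at
0.5-mm intervals along a motorized catheter pullback, each paired with a
manually segmented five-class mask (background, lumen, media+plaque,
calcification, stent).  This module emulates those data with full analytic
ground truth so that segmentation, clinical metrics and evaluation can be
tested end to end without clinical images.

A phantom vessel is an ellipse-in-ellipse geometry: a dark lumen inside an
echogenic media+plaque annulus, optionally carrying calcified arcs (bright
leading edge with an acoustic shadow behind), a ring of bright stent struts,
a central catheter ring and an optional bright wire artifact.  Geometry
parameters evolve as a bounded random walk along the pullback so that frames
of one patient are correlated, and lesion attributes (stenosis,
calcification, stent) occupy contiguous frame runs — the within-patient
structure that makes patient-level data splitting matter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter

from ivusseg.masks import (
    BACKGROUND,
    CALCIFICATION,
    LUMEN,
    MEDIA_PLAQUE,
    STENT,
    LabelMask,
    write_mask,
)

#: maximum per-frame change of either lumen semi-axis along a pullback (mm)
MAX_LUMEN_STEP_MM = 0.08


class GeometryError(ValueError):
    """Vessel geometry violates its invariants."""


class ConfigError(ValueError):
    """Simulation configuration is invalid."""


@dataclass
class CalcArc:
    """One calcified arc: angular sector plus a radial band above the lumen border."""

    start_deg: float
    extent_deg: float
    radial_offset_mm: float
    thickness_mm: float


@dataclass
class VesselGeometry:
    """Analytic description of one cross-sectional frame.

    Angles are measured in degrees from the +x (column) axis toward +y
    (row) axis, i.e. in array coordinates; all radial quantities are in mm
    and are converted to pixels with ``pixel_spacing``.
    """

    lumen_center: tuple[float, float]  # (x, y) px
    lumen_radii: tuple[float, float]  # (a, b) semi-axes, mm
    lumen_rotation: float  # deg
    media_outer_radii: tuple[float, float]  # (a, b) mm
    calc_arcs: list[CalcArc] = field(default_factory=list)
    strut_angles: list[float] = field(default_factory=list)  # deg
    strut_ring_radius: float = 0.0  # mm
    wire_artifact_angle: float | None = None  # deg
    pixel_spacing: float = 0.02  # mm/px
    image_size: int = 256  # px

    def validate(self) -> None:
        a, b = self.lumen_radii
        A, B = self.media_outer_radii
        if a <= 0 or b <= 0:
            raise GeometryError("lumen semi-axes must be positive")
        if A <= a or B <= b:
            raise GeometryError("media outer radii must strictly exceed lumen radii")
        for arc in self.calc_arcs:
            if not 0 < arc.extent_deg <= 360:
                raise GeometryError(f"calc arc extent must be in (0, 360], got {arc.extent_deg}")
            if arc.thickness_mm <= 0:
                raise GeometryError("calc arc thickness must be positive")
        if self.strut_angles and self.strut_ring_radius < max(a, b):
            raise GeometryError("strut ring radius must be >= max lumen radius")
        if self.pixel_spacing <= 0 or self.image_size <= 0:
            raise GeometryError("pixel_spacing and image_size must be positive")


@dataclass
class GroundTruthRecord:
    """Analytic per-frame ground truth used by recovery tests."""

    true_lumen_area: float  # mm^2, pi*a*b
    true_calc_arc: float  # deg, union of declared arcs
    true_quadrant_count: int  # 0-4, fixed 90-deg sectors
    true_strut_positions: list[tuple[float, float]]  # (x, y) px
    has_calcification: bool
    has_stent: bool

    @property
    def narrowed(self) -> bool:
        return self.true_lumen_area < 4.0

    @property
    def severe_calc(self) -> bool:
        return self.true_quadrant_count > 2


@dataclass
class BModeFrame:
    """Grayscale intensity grid in [0, 1] with physical pixel spacing."""

    image: np.ndarray
    pixel_spacing: float


@dataclass
class PullbackSequence:
    """Ordered frames of one synthetic patient (the unit of the data split)."""

    patient_id: str
    frames: list[tuple[BModeFrame, LabelMask, GroundTruthRecord]]
    frame_interval: float = 0.5  # mm between consecutive frames

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class SimConfig:
    """Dataset-level simulation parameters.

    The lesion-prevalence defaults reproduce the composition of the study
    dataset this generator emulates: 59.1% of frames show calcification and
    12.3% show a stent; 28.7% of calcified frames carry severe (more than
    two-quadrant) calcification.
    """

    n_patients: int = 24
    frames_per_patient: int = 156
    calc_frame_fraction: float = 0.591
    stent_frame_fraction: float = 0.123
    narrowed_fraction: float = 0.30
    severe_calc_fraction: float = 0.287
    speckle_scale: float = 0.35
    shadow_attenuation: float = 0.15
    wire_artifact_fraction: float = 0.25
    pixel_spacing: float = 0.02  # mm/px
    image_size: int = 256  # px
    frame_interval: float = 0.5  # mm
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_patients <= 0 or self.frames_per_patient <= 0:
            raise ConfigError("n_patients and frames_per_patient must be positive")
        for name in (
            "calc_frame_fraction",
            "stent_frame_fraction",
            "narrowed_fraction",
            "severe_calc_fraction",
            "wire_artifact_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.shadow_attenuation <= 1.0:
            raise ConfigError("shadow_attenuation must be in [0, 1]")
        if self.speckle_scale < 0:
            raise ConfigError("speckle_scale must be non-negative")
        if self.pixel_spacing <= 0 or self.image_size <= 0:
            raise ConfigError("pixel_spacing and image_size must be positive")


# ---------------------------------------------------------------------------
# analytic ground truth


def _merge_intervals(arcs: Sequence[CalcArc]) -> list[tuple[float, float]]:
    """Union of angular intervals on the circle, as [start, end) pairs in [0, 360)."""
    segs: list[tuple[float, float]] = []
    for arc in arcs:
        s = arc.start_deg % 360.0
        e = s + min(arc.extent_deg, 360.0)
        if e <= 360.0:
            segs.append((s, e))
        else:  # wraps past 360
            segs.append((s, 360.0))
            segs.append((0.0, e - 360.0))
    if not segs:
        return []
    segs.sort()
    merged = [list(segs[0])]
    for s, e in segs[1:]:
        if s <= merged[-1][1] + 1e-9:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def true_calc_arc_deg(geom: VesselGeometry) -> float:
    """Total angular extent (deg) of the union of declared calcified arcs."""
    return float(min(360.0, sum(e - s for s, e in _merge_intervals(geom.calc_arcs))))


def true_quadrant_count(geom: VesselGeometry) -> int:
    """Number of fixed 90-degree sectors intersected by the calcified arcs."""
    quadrants = set()
    for s, e in _merge_intervals(geom.calc_arcs):
        for q in range(4):
            q0, q1 = 90.0 * q, 90.0 * (q + 1)
            if s < q1 and e > q0:
                quadrants.add(q)
    return len(quadrants)


def ground_truth_for(geom: VesselGeometry) -> GroundTruthRecord:
    """Analytic ground-truth record for one geometry."""
    a, b = geom.lumen_radii
    cx, cy = geom.lumen_center
    r_px = geom.strut_ring_radius / geom.pixel_spacing
    struts = [
        (cx + r_px * np.cos(np.deg2rad(t)), cy + r_px * np.sin(np.deg2rad(t)))
        for t in geom.strut_angles
    ]
    return GroundTruthRecord(
        true_lumen_area=float(np.pi * a * b),
        true_calc_arc=true_calc_arc_deg(geom),
        true_quadrant_count=true_quadrant_count(geom),
        true_strut_positions=struts,
        has_calcification=bool(geom.calc_arcs),
        has_stent=bool(geom.strut_angles),
    )


# ---------------------------------------------------------------------------
# rasterization


def _polar_grids(geom: VesselGeometry) -> tuple[np.ndarray, np.ndarray]:
    """(radius px, angle deg in [0, 360)) about the lumen center, array coords."""
    n = geom.image_size
    cx, cy = geom.lumen_center
    yy, xx = np.mgrid[0:n, 0:n].astype(np.float64)
    dx, dy = xx - cx, yy - cy
    r = np.hypot(dx, dy)
    theta = np.rad2deg(np.arctan2(dy, dx)) % 360.0
    return r, theta


def _ellipse_radius_px(geom: VesselGeometry, theta_deg: np.ndarray, radii_mm: tuple[float, float]) -> np.ndarray:
    """Polar radius (px) of an ellipse boundary at each angle, honoring rotation."""
    a, b = (radii_mm[0] / geom.pixel_spacing, radii_mm[1] / geom.pixel_spacing)
    t = np.deg2rad(theta_deg - geom.lumen_rotation)
    return a * b / np.sqrt((b * np.cos(t)) ** 2 + (a * np.sin(t)) ** 2)


def _angle_in_arc(theta: np.ndarray, start: float, extent: float) -> np.ndarray:
    d = (theta - start) % 360.0
    return d <= extent


def _strut_radius_px(geom: VesselGeometry) -> int:
    # struts are ~0.1-mm metallic points; at least one pixel at any resolution
    return max(1, int(round(0.05 / geom.pixel_spacing)))


def rasterize_mask(geom: VesselGeometry) -> LabelMask:
    """Rasterize a geometry into a five-class label mask.

    Classes partition the image: calcification carves pixels out of the
    media+plaque annulus (it never extends past the adventitia), and stent
    struts are stamped last so they may overlap the lumen border, matching
    their clinical appearance.
    """
    geom.validate()
    n = geom.image_size
    r, theta = _polar_grids(geom)
    labels = np.zeros((n, n), dtype=np.uint8)

    media_r = _ellipse_radius_px(geom, theta, geom.media_outer_radii)
    lumen_r = _ellipse_radius_px(geom, theta, geom.lumen_radii)
    labels[r <= media_r] = MEDIA_PLAQUE
    labels[r <= lumen_r] = LUMEN

    for arc in geom.calc_arcs:
        band_lo = lumen_r + arc.radial_offset_mm / geom.pixel_spacing
        band_hi = band_lo + arc.thickness_mm / geom.pixel_spacing
        sel = (
            _angle_in_arc(theta, arc.start_deg, arc.extent_deg)
            & (r >= band_lo)
            & (r <= band_hi)
            & (labels == MEDIA_PLAQUE)
        )
        labels[sel] = CALCIFICATION

    if geom.strut_angles:
        ring_px = geom.strut_ring_radius / geom.pixel_spacing
        srad = _strut_radius_px(geom)
        cx, cy = geom.lumen_center
        yy, xx = np.mgrid[0:n, 0:n]
        for t in geom.strut_angles:
            sx = cx + ring_px * np.cos(np.deg2rad(t))
            sy = cy + ring_px * np.sin(np.deg2rad(t))
            sel = (xx - sx) ** 2 + (yy - sy) ** 2 <= srad**2
            labels[sel] = STENT

    return LabelMask(labels, pixel_spacing=geom.pixel_spacing)


# ---------------------------------------------------------------------------
# B-mode rendering

_ECHO = {
    BACKGROUND: 0.20,  # adventitia / perivascular speckle
    LUMEN: 0.06,  # anechoic blood pool
    MEDIA_PLAQUE: 0.50,
    CALCIFICATION: 0.95,  # bright leading edge
    STENT: 1.00,
}

_CATHETER_RADIUS_MM = 0.35
_PSF_SIGMA_PX = 0.7
_STRUT_SHADOW_HALF_DEG = 4.0
_WIRE_HALF_DEG = 1.5


def echogenicity_map(geom: VesselGeometry, config: SimConfig) -> np.ndarray:
    """Deterministic (speckle-free) intensity map in [0, 1].

    Tissue echogenicity from the rasterized classes, plus the central
    catheter ring, acoustic shadows radially outward of calcification and
    struts, and an optional bright wire-artifact ray.
    """
    mask = rasterize_mask(geom)
    img = np.empty(mask.labels.shape, dtype=np.float64)
    for cls, v in _ECHO.items():
        img[mask.labels == cls] = v

    n = geom.image_size
    r, theta = _polar_grids(geom)
    lumen_r = _ellipse_radius_px(geom, theta, geom.lumen_radii)

    # acoustic shadow: attenuate everything radially outward of each occluder
    for arc in geom.calc_arcs:
        band_hi = lumen_r + (arc.radial_offset_mm + arc.thickness_mm) / geom.pixel_spacing
        sel = _angle_in_arc(theta, arc.start_deg, arc.extent_deg) & (r > band_hi)
        img[sel] *= config.shadow_attenuation
    if geom.strut_angles:
        ring_px = geom.strut_ring_radius / geom.pixel_spacing
        srad = _strut_radius_px(geom)
        for t in geom.strut_angles:
            sel = _angle_in_arc(theta, t - _STRUT_SHADOW_HALF_DEG, 2 * _STRUT_SHADOW_HALF_DEG) & (
                r > ring_px + srad
            )
            img[sel] *= config.shadow_attenuation

    # wire artifact: bright ray from the catheter outward (a common failure
    # mode of clinical segmentation near guide wires)
    if geom.wire_artifact_angle is not None:
        sel = _angle_in_arc(theta, geom.wire_artifact_angle - _WIRE_HALF_DEG, 2 * _WIRE_HALF_DEG)
        img[sel] = np.maximum(img[sel], 0.75)

    # catheter: bright ring around a transducer void at the image center
    cath_px = _CATHETER_RADIUS_MM / geom.pixel_spacing
    cc = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n].astype(np.float64)
    rc = np.hypot(xx - cc, yy - cc)
    img[rc <= cath_px] = 0.03
    img[np.abs(rc - cath_px) <= 1.0] = 0.85

    img = gaussian_filter(img, _PSF_SIGMA_PX, mode="nearest")
    return np.clip(img, 0.0, 1.0)


def render_bmode(geom: VesselGeometry, config: SimConfig, rng: np.random.Generator) -> BModeFrame:
    """Render one B-mode frame: echogenicity map times multiplicative speckle.

    The speckle field is Rayleigh-distributed (the envelope statistics of
    fully developed ultrasound speckle), smoothed with a small Gaussian to
    give it a finite correlation length, and normalized to unit mean so that
    ``speckle_scale`` controls only its contrast; ``speckle_scale=0``
    returns the deterministic map exactly.
    """
    geom.validate()
    config.validate()
    base = echogenicity_map(geom, config)
    if config.speckle_scale > 0:
        n = geom.image_size
        ray = rng.rayleigh(scale=1.0, size=(n, n))
        ray = gaussian_filter(ray, 0.8, mode="wrap")
        ray /= ray.mean()
        base = base * (1.0 + config.speckle_scale * (ray - 1.0))
    return BModeFrame(np.clip(base, 0.0, 1.0), pixel_spacing=geom.pixel_spacing)


# ---------------------------------------------------------------------------
# patient-level geometry trajectories

# lumen mean-radius ranges (mm): normal segments vs narrowed (area < 4 mm^2
# corresponds to mean radius < 1.128 mm)
_R_NORMAL = (1.20, 1.50)
_R_NARROW = (0.70, 1.00)
_WALL_RANGE = (0.50, 0.90)  # media thickness, mm
_ARC_SEVERE = (200.0, 320.0)  # deg, guarantees > 2 quadrants
_ARC_MILD = (20.0, 160.0)  # deg, placed inside two adjacent quadrants


def _snap_arc(start: float, extent: float, margin: float = 3.0) -> tuple[float, float]:
    """Keep arc endpoints at least ``margin`` degrees away from quadrant edges.

    An endpoint within ``margin`` of a multiple of 90 is pulled inward
    (shrinking the arc), so every quadrant the declared arc touches is
    overlapped by at least ``margin`` degrees and every quadrant it avoids
    is cleared by at least ``margin`` — which keeps the analytic quadrant
    count recoverable from rasterized pixels despite ~1-degree angular
    jitter of the pixel-centroid reference.
    """
    end = start + extent
    q = 90.0 * round(start / 90.0)
    if abs(start - q) < margin:
        start = q + margin
    q = 90.0 * round(end / 90.0)
    if abs(end - q) < margin:
        end = q - margin
    extent = max(end - start, 10.0)
    return start % 360.0, float(min(extent, 360.0))


def _contiguous_run(rng: np.random.Generator, n: int, fraction: float) -> np.ndarray:
    """Boolean run mask: Binomial(n, fraction) frames in one contiguous block."""
    mask = np.zeros(n, dtype=bool)
    length = int(rng.binomial(n, fraction))
    if length > 0:
        start = int(rng.integers(0, n - length + 1))
        mask[start : start + length] = True
    return mask


def _clamp_steps(values: np.ndarray, max_step: float) -> np.ndarray:
    """Limit consecutive differences to ±max_step, walking left to right."""
    out = values.copy()
    for i in range(1, out.size):
        d = np.clip(out[i] - out[i - 1], -max_step, max_step)
        out[i] = out[i - 1] + d
    return out


def _smooth_profile(
    rng: np.random.Generator,
    base: np.ndarray,
    walk_sigma: float,
    lo: float,
    hi: float,
    max_step: float,
) -> np.ndarray:
    """Gaussian-filtered target profile + reflected random walk, step-clamped."""
    prof = gaussian_filter(base, sigma=2.0, mode="nearest")
    steps = rng.normal(0.0, walk_sigma, size=base.size)
    walk = np.cumsum(steps)
    prof = prof + walk - walk.mean()
    # reflect into [lo, hi]
    prof = np.where(prof > hi, 2 * hi - prof, prof)
    prof = np.where(prof < lo, 2 * lo - prof, prof)
    prof = np.clip(prof, lo, hi)
    return np.clip(_clamp_steps(prof, max_step), lo, hi)


def sample_patient(config: SimConfig, rng: np.random.Generator) -> list[VesselGeometry]:
    """Sample one patient's smooth geometry trajectory along the pullback.

    Lesion attributes (stenosis, calcification, stent segment) occupy
    contiguous frame runs whose lengths are Binomial(frames, fraction), so
    dataset-level prevalences converge to the configured fractions while
    frames within a patient stay strongly correlated.
    """
    config.validate()
    n = config.frames_per_patient
    half_fov_mm = config.image_size * config.pixel_spacing / 2.0

    narrowed = _contiguous_run(rng, n, config.narrowed_fraction)
    calc_run = _contiguous_run(rng, n, config.calc_frame_fraction)
    stent_run = _contiguous_run(rng, n, config.stent_frame_fraction)

    # lumen mean radius: normal plateau with a narrowed dip
    r_hi = rng.uniform(*_R_NORMAL)
    r_lo = rng.uniform(*_R_NARROW)
    base_r = np.where(narrowed, r_lo, r_hi)
    mean_r = _smooth_profile(rng, base_r, 0.01, _R_NARROW[0], _R_NORMAL[1], MAX_LUMEN_STEP_MM)

    # eccentricity (b/a) and rotation drift slowly
    ecc = _smooth_profile(rng, np.full(n, rng.uniform(0.75, 0.95)), 0.004, 0.70, 1.00, 0.02)
    # the semi-axes themselves carry the smoothness contract
    ax = _clamp_steps(mean_r / np.sqrt(ecc), MAX_LUMEN_STEP_MM)
    bx = _clamp_steps(mean_r * np.sqrt(ecc), MAX_LUMEN_STEP_MM)
    rot = np.cumsum(rng.normal(0.0, 1.5, size=n)) + rng.uniform(0.0, 360.0)

    wall = _smooth_profile(rng, np.full(n, rng.uniform(*_WALL_RANGE)), 0.006, *_WALL_RANGE, 0.03)

    # lumen center wanders slightly around the image center
    cc = (config.image_size - 1) / 2.0
    off_mm = 0.18
    cx = _smooth_profile(rng, np.full(n, rng.uniform(-off_mm, off_mm)), 0.004, -off_mm, off_mm, 0.02)
    cy = _smooth_profile(rng, np.full(n, rng.uniform(-off_mm, off_mm)), 0.004, -off_mm, off_mm, 0.02)

    # calcification: one arc whose span/anchor drift; severe runs span > 2 quadrants
    severe = rng.random() < config.severe_calc_fraction
    if severe:
        ext0 = rng.uniform(*_ARC_SEVERE)
        start0 = rng.uniform(0.0, 360.0)
    else:
        ext0 = rng.uniform(*_ARC_MILD)
        # anchor the arc inside two adjacent quadrants so it stays mild
        q = int(rng.integers(0, 4))
        start0 = 90.0 * q + rng.uniform(0.0, max(1e-6, 180.0 - ext0))
    ext = _smooth_profile(rng, np.full(n, ext0), 0.5, 10.0, 340.0 if severe else 160.0, 4.0)
    arc_start = start0 + np.cumsum(rng.normal(0.0, 0.5, size=n))
    calc_off = rng.uniform(0.02, 0.08)
    calc_thick = rng.uniform(0.15, 0.30)

    # stent: 6-10 struts, evenly spaced with jitter, ring follows the lumen
    n_struts = int(rng.integers(6, 11))
    strut_base = rng.uniform(0.0, 360.0 / n_struts)
    strut_jitter = rng.normal(0.0, 3.0, size=n_struts)
    strut_drift = np.cumsum(rng.normal(0.0, 0.4, size=n))

    wire_angle = rng.uniform(0.0, 360.0) if rng.random() < config.wire_artifact_fraction else None

    geoms: list[VesselGeometry] = []
    for i in range(n):
        a, b = ax[i], bx[i]
        # keep the adventitia inside the field of view
        max_outer = 0.94 * half_fov_mm - max(abs(cx[i]), abs(cy[i]))
        w = min(wall[i], max(0.35, max_outer - max(a, b)))
        arcs = []
        if calc_run[i]:
            thick = min(calc_thick, w - calc_off - 0.05)
            s_i, e_i = _snap_arc(arc_start[i] % 360.0, ext[i])
            arcs = [CalcArc(s_i, e_i, calc_off, max(0.10, thick))]
        struts: list[float] = []
        ring = 0.0
        if stent_run[i]:
            ring = max(a, b) + 0.06
            struts = [
                (strut_base + 360.0 * k / n_struts + strut_jitter[k] + strut_drift[i]) % 360.0
                for k in range(n_struts)
            ]
        geoms.append(
            VesselGeometry(
                lumen_center=(cc + cx[i] / config.pixel_spacing, cc + cy[i] / config.pixel_spacing),
                lumen_radii=(float(a), float(b)),
                lumen_rotation=float(rot[i]),
                media_outer_radii=(float(a + w), float(b + w)),
                calc_arcs=arcs,
                strut_angles=struts,
                strut_ring_radius=float(ring),
                wire_artifact_angle=wire_angle,
                pixel_spacing=config.pixel_spacing,
                image_size=config.image_size,
            )
        )
    return geoms


# ---------------------------------------------------------------------------
# dataset generation


def generate_sequences(config: SimConfig) -> list[PullbackSequence]:
    """Generate all patients' pullback sequences in memory.

    Deterministic: identical config (including ``rng_seed``) yields a
    bit-identical dataset.  Each patient draws from an independently spawned
    child stream, so the per-patient content does not depend on generation
    order.
    """
    config.validate()
    seqs: list[PullbackSequence] = []
    children = np.random.SeedSequence(config.rng_seed).spawn(config.n_patients)
    for p, child in enumerate(children):
        rng = np.random.default_rng(child)
        frames = []
        for geom in sample_patient(config, rng):
            mask = rasterize_mask(geom)
            frame = render_bmode(geom, config, rng)
            frames.append((frame, mask, ground_truth_for(geom)))
        seqs.append(
            PullbackSequence(patient_id=f"P{p:03d}", frames=frames, frame_interval=config.frame_interval)
        )
    return seqs


def write_frame_png(frame: BModeFrame, path: str | Path) -> None:
    """Write a B-mode frame as an 8-bit grayscale PNG."""
    img8 = np.clip(np.round(frame.image * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(img8, mode="L").save(Path(path), format="PNG")


def generate_dataset(config: SimConfig, out_dir: str | Path) -> tuple[list[PullbackSequence], Path]:
    """Generate the dataset and write frames, masks and a manifest to disk.

    Layout: ``<out>/P000/frame_0000.png`` (grayscale) and
    ``<out>/P000/mask_0000.png`` (RGB palette), plus ``<out>/manifest.csv``
    mapping every frame to its patient together with the analytic
    ground-truth columns.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out}: {exc}") from exc
    seqs = generate_sequences(config)
    rows = []
    for seq in seqs:
        pdir = out / seq.patient_id
        pdir.mkdir(exist_ok=True)
        for i, (frame, mask, gt) in enumerate(seq.frames):
            fpath = pdir / f"frame_{i:04d}.png"
            mpath = pdir / f"mask_{i:04d}.png"
            write_frame_png(frame, fpath)
            write_mask(mask, mpath)
            rows.append(
                {
                    "patient_id": seq.patient_id,
                    "frame_index": i,
                    "frame_path": str(fpath.relative_to(out)),
                    "mask_path": str(mpath.relative_to(out)),
                    "true_lumen_area_mm2": gt.true_lumen_area,
                    "true_calc_arc_deg": gt.true_calc_arc,
                    "true_quadrant_count": gt.true_quadrant_count,
                    "n_struts": len(gt.true_strut_positions),
                    "has_calcification": gt.has_calcification,
                    "has_stent": gt.has_stent,
                    "narrowed": gt.narrowed,
                    "severe_calc": gt.severe_calc,
                }
            )
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return seqs, manifest
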
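"""Voronoi rasterization of a visual field.

A sparse deviation vector is rendered as a dense 8-bit grayscale image: every
pixel inside the inscribed circle (the central 30 degrees of field) takes the
grayscale of its nearest test point, so the image is the Voronoi parcellation
of the grid coloured by defect depth; pixels outside the circle are zero.

Grayscale mapping: the fixed window [-35, +5] dB is mapped affinely onto
[0, 255] (values clamped to the window ends, rounding half-up), so absolute
severity maps to absolute darkness and images are comparable across patients
and devices.

Geometry: pixel (i, j) of a size-S image has its centre at degree coordinates
((j + 0.5 - S/2) / s, (S/2 - i - 0.5) / s) with s = (S/2) / 30 pixels per
degree; y increases upward in degree space. Equidistant pixels go to the
lowest point index. Test points beyond 30 degrees eccentricity are clamped
onto the circle boundary before rendering.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .patterns import PatternId
from .records import Eye, VFRecord

#: dB window mapped onto [0, 255]
GRAY_WINDOW = (-35.0, 5.0)
#: eccentricity represented by the inscribed circle, degrees
FIELD_RADIUS_DEG = 30.0


@dataclass(frozen=True)
class VoronoiImage:
    """A rendered visual field: square uint8 raster with circular mask."""

    pixels: np.ndarray
    pattern_id: PatternId

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=np.uint8)
        if px.ndim != 2 or px.shape[0] != px.shape[1]:
            raise ValueError(f"pixels must be square, got {px.shape}")
        px.setflags(write=False)
        object.__setattr__(self, "pixels", px)

    @property
    def size(self) -> int:
        return self.pixels.shape[0]

    @property
    def scale(self) -> float:
        """Pixels per degree."""
        return (self.size / 2) / FIELD_RADIUS_DEG

    @property
    def center(self) -> tuple[float, float]:
        """Pixel coordinates of fixation (row, col)."""
        return (self.size / 2, self.size / 2)


def deviation_to_gray(d) -> np.ndarray | int:
    """Affine map of deviation dB onto 8-bit grayscale, rounding half-up.

    Monotone non-decreasing; the window ends of GRAY_WINDOW map to 0 and 255.
    """
    d = np.asarray(d, dtype=float)
    if not np.all(np.isfinite(d)):
        raise ValueError("deviation must be finite")
    lo, hi = GRAY_WINDOW
    clipped = np.clip(d, lo, hi)
    g = np.floor(255.0 * (clipped - lo) / (hi - lo) + 0.5).astype(np.uint8)
    return int(g) if g.ndim == 0 else g


def _pixel_centers_deg(size: int) -> tuple[np.ndarray, np.ndarray]:
    s = (size / 2) / FIELD_RADIUS_DEG
    j = np.arange(size)
    i = np.arange(size)
    x = (j + 0.5 - size / 2) / s
    y = (size / 2 - i - 0.5) / s
    return np.meshgrid(x, y)  # X varies along columns, Y along rows


def _clamped_sites(record: VFRecord) -> np.ndarray:
    pts = record.pattern.points.copy()
    ecc = np.hypot(pts[:, 0], pts[:, 1])
    over = ecc > FIELD_RADIUS_DEG
    if np.any(over):
        pts[over] *= (FIELD_RADIUS_DEG / ecc[over])[:, None]
    return pts


def rasterize(record: VFRecord, size: int = 224) -> VoronoiImage:
    """Render a right-eye-format record as a Voronoi grayscale image.

    Each in-circle pixel takes the grayscale of its Euclidean-nearest test
    point (ties to the lowest point index); out-of-circle pixels are 0.
    """
    if size < 32 or size % 2:
        raise ValueError(f"size must be even and >= 32, got {size}")
    if record.eye is Eye.L and not record.right_eye_format:
        raise ValueError("record must be in right-eye format (run to_right_eye)")
    sites = _clamped_sites(record)
    grays = deviation_to_gray(record.deviations)
    X, Y = _pixel_centers_deg(size)
    # squared distance stack (k, S, S); argmin picks the lowest index on ties
    d2 = (X[None] - sites[:, 0, None, None]) ** 2 \
        + (Y[None] - sites[:, 1, None, None]) ** 2
    nearest = np.argmin(d2, axis=0)
    img = grays[nearest]
    img[X ** 2 + Y ** 2 > FIELD_RADIUS_DEG ** 2] = 0
    return VoronoiImage(img, record.pattern_id)


def apply_mask(image: VoronoiImage | np.ndarray):
    """Zero every pixel strictly outside the inscribed circle (idempotent)."""
    if isinstance(image, VoronoiImage):
        return VoronoiImage(mask_array(np.array(image.pixels)), image.pattern_id)
    return mask_array(np.asarray(image))


def mask_array(pixels: np.ndarray) -> np.ndarray:
    """Circular-mask a square raster in place and return it."""
    size = pixels.shape[-1]
    if pixels.shape[-2] != size:
        raise ValueError(f"image must be square, got {pixels.shape}")
    i, j = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    r2 = (i + 0.5 - size / 2) ** 2 + (j + 0.5 - size / 2) ** 2
    pixels[..., r2 > (size / 2) ** 2] = 0
    return pixels


def to_png(image: VoronoiImage, path) -> None:
    """Write the raster as a lossless 8-bit grayscale PNG."""
    from PIL import Image

    Image.fromarray(np.asarray(image.pixels), mode="L").save(path, format="PNG")


def png_filename(record: VFRecord) -> str:
    return f"{record.patient_id}_{record.eye.value}_{record.exam_date.isoformat()}.png"
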
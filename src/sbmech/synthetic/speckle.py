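"""Synthetic speckle images and displacement-warped frame sequences.

Mimics the airbrushed random speckle pattern used for digital image
correlation on a flat specimen face imaged by a high-speed camera. Frame 0
is the reference; each later frame is the reference resampled through a
prescribed per-pixel displacement field with smooth (cubic) interpolation so
subpixel information survives for DIC.

Convention: the field (u, v) gives the displacement in pixels (u = columns,
v = rows, v positive downward) of the material seen at each pixel; the
deformed frame is f(x - u(x), y - v(y)). For the small strains of interest
the distinction from a material-point (Lagrangian) field is far below DIC
measurement tolerance.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates, spline_filter


@dataclass
class SpeckleTruth:
    """Ground-truth fields per frame (lists of (u, v) pixel arrays)."""

    fields: list[tuple[np.ndarray, np.ndarray]]
    seed: int
    speckle_density: float


def make_speckle_image(
    shape: tuple[int, int],
    speckle_density: float = 0.35,
    spot_sigma: float = 1.2,
    seed: int = 0,
) -> np.ndarray:
    """Random speckle texture in [0, 1]: dark spots on a light background."""
    if not 0 < speckle_density < 1:
        raise ValueError("speckle_density must be in (0, 1)")
    rng = np.random.default_rng(seed)
    dots = (rng.random(shape) < speckle_density).astype(float)
    im = gaussian_filter(dots, spot_sigma)
    lo, hi = im.min(), im.max()
    if hi > lo:
        im = (im - lo) / (hi - lo)
    return 1.0 - im


def render_speckle_sequence(
    fields: list[tuple[np.ndarray, np.ndarray]],
    image_size: tuple[int, int] = (256, 256),
    speckle_density: float = 0.35,
    seed: int = 0,
    reference: np.ndarray | None = None,
) -> tuple[np.ndarray, SpeckleTruth]:
    """Render a frame stack from per-frame displacement fields.

    ``fields[t]`` is an ``(u, v)`` pair of full-image pixel arrays for frame
    ``t + 1``; frame 0 is the untouched reference. Returns a float stack of
    shape ``(1 + len(fields), H, W)`` with intensities in [0, 1].
    """
    if reference is None:
        reference = make_speckle_image(image_size, speckle_density, seed=seed)
    ref = np.asarray(reference, dtype=float)
    h, w = ref.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    # cubic spline coefficients of the reference, computed once per sequence
    ref_spline = spline_filter(ref, order=3, mode="nearest")
    frames = [ref]
    stored = []
    limit = min(h, w) / 4.0
    for i, (u, v) in enumerate(fields):
        u = np.asarray(u, dtype=float)
        v = np.asarray(v, dtype=float)
        if u.shape != ref.shape or v.shape != ref.shape:
            raise ValueError(
                f"frame {i + 1}: displacement field shape {u.shape}/{v.shape} "
                f"does not cover the full image {ref.shape}"
            )
        if np.max(np.abs(u)) >= limit or np.max(np.abs(v)) >= limit:
            raise ValueError(f"frame {i + 1}: displacement exceeds image_size/4")
        warped = map_coordinates(ref_spline, [yy - v, xx - u], order=3,
                                 mode="nearest", prefilter=False)
        frames.append(warped)
        stored.append((u, v))
    truth = SpeckleTruth(fields=stored, seed=seed, speckle_density=speckle_density)
    return np.stack(frames), truth


def uniform_field(shape: tuple[int, int], u: float, v: float) -> tuple[np.ndarray, np.ndarray]:
    """Rigid translation field (pixels)."""
    return np.full(shape, float(u)), np.full(shape, float(v))


def compression_field(
    shape: tuple[int, int], strain: float, fixed_row: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform vertical compression by ``strain`` (fraction, compression
    positive) about ``fixed_row`` (default: bottom row fixed, upper material
    moves down toward it as in a platen test with a fixed base)."""
    h, w = shape
    if fixed_row is None:
        fixed_row = h - 1
    rows = np.arange(h, dtype=float)[:, None]
    v = strain * (fixed_row - rows)  # positive (downward) above the fixed row
    return np.zeros(shape), np.broadcast_to(v, shape).copy()
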
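"""Subset-based 2-D digital image correlation, layer strain extraction, and
synchronization of image-derived strain with the load channel.

Each square subset of the reference speckle image is located in the deformed
image by maximum zero-normalized cross-correlation (ZNCC) within a search
window, then refined to subpixel precision by a quadratic fit to the 3x3
correlation neighborhood. Layer strains follow the extensometer convention
used for subchondral bone faces: the relative axial displacement of two
horizontal bands (the layer bounds) divided by the gauge length between them
(2 mm by default), compression positive.

Defaults (subset 31 px, step 8 px, search radius 20 px, acceptance score
0.6) are stated, configurable choices; commercial DIC packages do not
publish theirs.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates, spline_filter
from scipy.signal import find_peaks
from skimage.feature import match_template

from .mechanics import LoadDisplacementRecord, compute_stress, cycle_sample_bounds

logger = logging.getLogger(__name__)


@dataclass
class DisplacementField:
    """Subset-grid displacements in pixels. ``v`` is axial (row direction,
    positive downward = toward the specimen base); ``score`` is the ZNCC peak
    value in [-1, 1]; subsets with score below the acceptance threshold or
    without texture are marked invalid."""

    x: np.ndarray  # (n,) subset center columns
    y: np.ndarray  # (n,) subset center rows
    u: np.ndarray  # (n,)
    v: np.ndarray  # (n,)
    score: np.ndarray  # (n,)
    valid: np.ndarray  # (n,) bool
    frame_index: int = 0


@dataclass
class LayerBounds:
    """Depths (mm below the mineralized interface) of the two horizontal
    bands whose relative displacement defines the layer strain."""

    upper_bound_depth: float
    lower_bound_depth: float

    def __post_init__(self) -> None:
        if not self.lower_bound_depth > self.upper_bound_depth:
            raise ValueError("lower bound must be deeper than upper bound")

    @property
    def gauge_length(self) -> float:
        return self.lower_bound_depth - self.upper_bound_depth


#: microCT ROI convention: superficial band 0.5-2.5 mm, deep 2.5-4.5 mm
#: below the mineralized interface, both with a 2 mm gauge
SUPERFICIAL_BOUNDS = LayerBounds(0.5, 2.5)
DEEP_BOUNDS = LayerBounds(2.5, 4.5)


@dataclass
class LayerStrainSeries:
    layer: str
    strain: np.ndarray  # % per analyzed frame
    stress: np.ndarray  # MPa matched per frame
    cycle_index: np.ndarray  # per frame
    frame_offset_s: float = 0.0


def _parabola_peak(cm: float, c0: float, cp: float) -> float:
    """3-point peak offset; fitted on log-correlation (exact for the
    Gaussian-shaped peaks a blurred speckle autocorrelation produces),
    falling back to a plain parabola when a neighbor is non-positive."""
    if min(cm, c0, cp) > 0:
        cm, c0, cp = math.log(cm), math.log(c0), math.log(cp)
    denom = cm - 2.0 * c0 + cp
    if denom >= 0:  # not a proper maximum along this axis
        return 0.0
    off = 0.5 * (cm - cp) / denom
    return float(np.clip(off, -1.0, 1.0))


def _subpixel_offset(cc: np.ndarray, py: int, px: int) -> tuple[float, float]:
    """Per-axis 3-point parabola offset of the correlation peak, (-1, 1) px."""
    oy = ox = 0.0
    if 1 <= py < cc.shape[0] - 1:
        oy = _parabola_peak(cc[py - 1, px], cc[py, px], cc[py + 1, px])
    if 1 <= px < cc.shape[1] - 1:
        ox = _parabola_peak(cc[py, px - 1], cc[py, px], cc[py, px + 1])
    return oy, ox


def _refine_gauss_newton(
    de: np.ndarray,
    gy: np.ndarray,
    gx: np.ndarray,
    tmpl: np.ndarray,
    cy: int,
    cx: int,
    v0: float,
    u0: float,
    iterations: int = 4,
) -> tuple[float, float, float]:
    """Translation-only Gauss-Newton refinement of one subset match.

    Minimizes the SSD between the mean/std-normalized reference subset and
    the cubic-interpolated deformed patch; reaches the interpolation noise
    floor (~1e-3 px) where the correlation-peak parabola saturates at its
    pixel-locking bias. Returns (v, u, ZNCC score at the refined position).
    """
    h = tmpl.shape[0] // 2
    dy, dx = np.mgrid[-h:h + 1, -h:h + 1].astype(float)
    yy = dy + cy
    xx = dx + cx
    t = tmpl - tmpl.mean()
    tn = np.linalg.norm(t)
    if tn == 0:
        return v0, u0, -1.0
    t /= tn
    # affine subset shape function (translation + first-order gradients), so
    # linearly varying displacement within the subset is modeled, not
    # aliased into the center translation. Steepest-descent images and the
    # Hessian come from the (fixed) template gradients, computed once.
    tgy = gy[cy - h:cy + h + 1, cx - h:cx + h + 1]
    tgx = gx[cy - h:cy + h + 1, cx - h:cx + h + 1]
    sd = np.stack([
        tgx.ravel(), (tgx * dx).ravel(), (tgx * dy).ravel(),
        tgy.ravel(), (tgy * dx).ravel(), (tgy * dy).ravel(),
    ])
    hess = sd @ sd.T
    try:
        hinv = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        return v0, u0, -1.0
    # p = (u, ux, uy, v, vx, vy)
    p = np.zeros(6)
    p[0], p[3] = u0, v0
    score = -1.0
    for _ in range(iterations):
        wy = yy + p[3] + p[4] * dx + p[5] * dy
        wx = xx + p[0] + p[1] * dx + p[2] * dy
        patch = map_coordinates(de, [wy, wx], order=3, mode="nearest",
                                prefilter=False)
        pc = patch - patch.mean()
        pn = np.linalg.norm(pc)
        if pn == 0:
            break
        score = float((pc / pn * t).sum())  # ZNCC at the current warp
        r = ((pc / pn - t) * pn).ravel()
        dp = -hinv @ (sd @ r)
        if not np.all(np.isfinite(dp)):
            break
        p += dp
        if max(abs(dp[0]), abs(dp[3])) < 1e-4:
            break
    if abs(p[3] - v0) > 1.5 or abs(p[0] - u0) > 1.5:  # diverged; keep the seed
        return v0, u0, score
    return p[3], p[0], score


def track_subsets(
    reference: np.ndarray,
    deformed: np.ndarray,
    subset_size: int = 31,
    step: int = 8,
    search_radius: int = 20,
    score_threshold: float = 0.6,
    rows: np.ndarray | None = None,
    frame_index: int = 0,
    subpixel: str = "parabola",
    initial: DisplacementField | None = None,
) -> DisplacementField:
    """Track a regular grid of subsets from ``reference`` to ``deformed``.

    ``rows`` optionally restricts the grid to specific center rows (used for
    layer-bound bands). ZNCC is invariant to global affine intensity changes
    of the deformed frame; featureless (zero-variance) subsets are marked
    invalid rather than raising. ``subpixel`` selects the refinement:
    ``parabola`` (3x3 correlation-peak fit) or ``gauss_newton`` (iterative
    interpolation-based refinement seeded by the parabola estimate, for
    small-strain work where pixel-locking bias matters).

    With ``subpixel='gauss_newton'`` an ``initial`` field from a neighboring
    frame (same grid) seeds the refinement directly, skipping the integer
    correlation search; any subset whose refined score falls below the
    threshold falls back to the full search.
    """
    ref = np.asarray(reference, dtype=float)
    de = np.asarray(deformed, dtype=float)
    if ref.shape != de.shape:
        raise ValueError("reference and deformed images must share a shape")
    if subset_size % 2 != 1:
        raise ValueError("subset_size must be odd")
    h = subset_size // 2
    H, W = ref.shape
    margin = h + search_radius  # default grid keeps search windows unclipped
    if rows is None:
        rows = np.arange(margin, H - margin, step)
    else:
        rows = np.asarray(rows, dtype=int)
        if np.any(rows < h) or np.any(rows >= H - h):
            raise ValueError("requested rows leave no room for the subset")
    cols = np.arange(margin, W - margin, step)
    if subpixel not in ("parabola", "gauss_newton"):
        raise ValueError("subpixel must be 'parabola' or 'gauss_newton'")
    gy = gx = de_spline = None
    if subpixel == "gauss_newton":
        gy, gx = np.gradient(ref)  # template gradients (fixed per subset)
        # cubic spline coefficients computed once per frame; the refiner
        # then interpolates with prefilter=False
        de_spline = spline_filter(de, order=3, mode="nearest")

    use_seed = (
        initial is not None
        and subpixel == "gauss_newton"
        and initial.x.size == len(rows) * len(cols)
    )
    xs, ys, us, vs, scores, valid = [], [], [], [], [], []
    i = 0
    for cy in rows:
        for cx in cols:
            tmpl = ref[cy - h:cy + h + 1, cx - h:cx + h + 1]
            ok = tmpl.std() > 0
            du = dv = 0.0
            sc = -1.0
            seeded = False
            if ok and use_seed and initial.valid[i]:
                dv, du, sc = _refine_gauss_newton(
                    de_spline, gy, gx, tmpl, cy, cx,
                    float(initial.v[i]), float(initial.u[i]),
                )
                seeded = sc >= score_threshold
                ok = seeded or ok
            if ok and not seeded:
                y0 = max(0, cy - h - search_radius)
                x0 = max(0, cx - h - search_radius)
                win = de[y0:cy + h + search_radius + 1, x0:cx + h + search_radius + 1]
                cc = match_template(win, tmpl)
                py, px = np.unravel_index(int(np.nanargmax(cc)), cc.shape)
                sc = float(cc[py, px])
                oy, ox = _subpixel_offset(cc, py, px)
                dv = (y0 + py) - (cy - h) + oy
                du = (x0 + px) - (cx - h) + ox
                ok = sc >= score_threshold
                if ok and subpixel == "gauss_newton":
                    dv, du, sc = _refine_gauss_newton(de_spline, gy, gx, tmpl, cy, cx, dv, du)
                    ok = sc >= score_threshold
            xs.append(cx)
            ys.append(cy)
            us.append(du)
            vs.append(dv)
            scores.append(sc)
            valid.append(ok)
            i += 1
    return DisplacementField(
        x=np.array(xs), y=np.array(ys), u=np.array(us), v=np.array(vs),
        score=np.array(scores), valid=np.array(valid), frame_index=frame_index,
    )


def layer_strain(
    field: DisplacementField,
    bounds: LayerBounds,
    pixel_size: float,
    interface_row: float = 0.0,
    band_half_width_px: float = 8.0,
) -> float:
    """Layer strain in % from the relative axial displacement of the bound
    bands: 100 x (mean v at upper bound - mean v at lower bound) x
    pixel_size / gauge_length. Compression positive (the upper bound moves
    toward the fixed base more than the lower one).

    ``pixel_size`` in mm/px; bound depths are taken relative to
    ``interface_row`` (the mineralized interface in image rows).
    """
    means = []
    for name, depth in (("upper", bounds.upper_bound_depth), ("lower", bounds.lower_bound_depth)):
        row = interface_row + depth / pixel_size
        sel = field.valid & (np.abs(field.y - row) <= band_half_width_px)
        if not np.any(sel):
            raise ValueError(f"no valid subsets in the {name}-bound band at depth {depth} mm")
        means.append(float(field.v[sel].mean()))
    v_upper, v_lower = means
    return 100.0 * (v_upper - v_lower) * pixel_size / bounds.gauge_length


def _refined_peak_times(signal: np.ndarray, times: np.ndarray, distance: int) -> np.ndarray:
    """Peak times with local-quadratic subsample refinement."""
    sig = np.asarray(signal, dtype=float)
    peaks, _ = find_peaks(sig, distance=max(1, distance), prominence=0.25 * np.ptp(sig))
    out = []
    half = max(1, distance // 4)
    for p in peaks:
        lo, hi = max(0, p - half), min(sig.size, p + half + 1)
        if hi - lo >= 3:
            t = times[lo:hi]
            coef = np.polyfit(t - t[0], sig[lo:hi], 2)
            if coef[0] < 0:
                out.append(t[0] - coef[1] / (2 * coef[0]))
                continue
        out.append(times[p])
    return np.array(out)


def synchronize(
    strain_series: np.ndarray,
    actuator_displacement_video: np.ndarray,
    frame_times: np.ndarray,
    record: LoadDisplacementRecord,
    cycles: tuple[int, ...] = (1, 2, 3, 5, 9),
    frequency: float = 2.0,
    layer: str = "layer",
) -> LayerStrainSeries:
    """Align video frames to the load record and pair stress with strain.

    Per-cycle peaks of the video-derived actuator displacement are matched to
    per-cycle peaks of the record's displacement channel; a single time
    offset (mean peak-time difference, each peak refined by a local quadratic
    fit so subsampled video is not quantization-limited) maps frame times to
    record samples. Frames mapping into the requested cycles are returned
    with their matched stress.
    """
    strain_series = np.asarray(strain_series, dtype=float)
    frame_times = np.asarray(frame_times, dtype=float)
    video = np.asarray(actuator_displacement_video, dtype=float)
    if strain_series.size != frame_times.size or video.size != frame_times.size:
        raise ValueError("strain, video displacement and frame times must align")

    # median video frame spacing, for the peak-distance heuristic
    dt_video = float(np.median(np.diff(frame_times))) if frame_times.size > 1 else 1.0
    video_peaks = _refined_peak_times(video, frame_times, int(0.7 / (frequency * dt_video)))
    rec_peaks = _refined_peak_times(
        record.displacement, record.time, int(0.7 * record.sampling_rate / frequency)
    )
    # keep only record peaks within the video's (shifted) span
    if video_peaks.size == 0 or rec_peaks.size == 0:
        raise ValueError("no displacement peaks found in one of the channels")
    if rec_peaks.size > video_peaks.size:
        # video may cover a subset of cycles: match each video peak to the
        # nearest record peak after a coarse alignment on the first peak
        coarse = rec_peaks[0] - video_peaks[0]
        matched = []
        for vp in video_peaks:
            matched.append(rec_peaks[np.argmin(np.abs(rec_peaks - (vp + coarse)))])
        rec_use = np.array(matched)
    elif rec_peaks.size == video_peaks.size:
        rec_use = rec_peaks
    else:
        raise ValueError(
            f"peak counts differ: video has {video_peaks.size}, record has {rec_peaks.size}"
        )
    offset = float(np.mean(rec_use - video_peaks))

    stress = compute_stress(record.load, record.geometry)
    mapped_t = frame_times + offset
    frame_stress = np.interp(mapped_t, record.time, stress)

    # which cycle does each frame fall in? cycle k spans the stress minima
    # bracketing the k-th stress peak, mirroring segment_cycles
    spans = cycle_sample_bounds(stress, record.sampling_rate, frequency)
    cyc_idx = np.zeros(mapped_t.size, dtype=int)
    if spans:
        starts_t = record.time[np.array([s[0] for s in spans])]
        cyc_idx = np.searchsorted(starts_t, mapped_t, side="right")
        ends_t = record.time[spans[-1][2]]
        cyc_idx[mapped_t > ends_t] = 0  # beyond the last complete cycle
    keep = np.isin(cyc_idx, cycles)
    return LayerStrainSeries(
        layer=layer,
        strain=strain_series[keep],
        stress=frame_stress[keep],
        cycle_index=cyc_idx[keep],
        frame_offset_s=offset,
    )
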
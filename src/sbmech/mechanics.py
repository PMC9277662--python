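"""Per-cycle stiffness, normalized hysteresis and apparent strain from
load-displacement records of cyclic compression tests.

Definitions follow the standard cartilage-bone testing conventions:

* apparent stress = load / load-bearing cross-section (MPa);
* engineering strain = compressive length change / length at end of preload,
  reported in %, compression positive;
* stiffness (apparent modulus) = ordinary least-squares slope of stress vs
  strain-as-fraction over the middle 50 % of a loading branch's stress range
  (MPa);
* normalized hysteresis = (loading work - unloading work) / loading work,
  each work term a trapezoid integral of stress over that branch's own
  strain span, so residual deformation counts as dissipated energy.

Cycles are split at stress extrema (the test is load-controlled) and indexed
from 1. Whole specimens are summarized at cycles 1, 2, 3, 5, 9, 19, ..., 99;
image-derived layers at cycles 1, 2, 3, 5 and 9.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np
from scipy.signal import find_peaks

if TYPE_CHECKING:  # avoid a circular import with the synthetic subpackage
    from .synthetic.protocol import SpecimenGeometry

logger = logging.getLogger(__name__)

#: Cycles analyzed for the whole (total) cartilage-bone specimen
TOTAL_CYCLES = (1, 2, 3, 5, 9, 19, 29, 39, 49, 59, 69, 79, 89, 99)
#: Cycles analyzed for the superficial/deep layers (camera-limited)
LAYER_CYCLES = (1, 2, 3, 5, 9)


@dataclass
class LoadDisplacementRecord:
    """Uniformly sampled time (s) / load (N) / displacement (mm) series.

    ``displacement`` is compressive shortening relative to the end of the
    preload hold (compression positive); ``reference_length`` is the specimen
    length at that instant and is the gauge for engineering strain.
    """

    time: np.ndarray
    load: np.ndarray
    displacement: np.ndarray
    sampling_rate: float
    geometry: "SpecimenGeometry"
    reference_length: float

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.load = np.asarray(self.load, dtype=float)
        self.displacement = np.asarray(self.displacement, dtype=float)
        n = self.time.size
        if self.load.size != n or self.displacement.size != n:
            raise ValueError("time, load and displacement must have equal length")
        if n >= 2:
            dt = np.diff(self.time)
            if np.any(dt <= 0):
                raise ValueError("time must be strictly increasing")
            if np.ptp(dt) > 1e-9:
                raise ValueError("time grid must be uniform within 1e-9 s")
            if abs(dt[0] - 1.0 / self.sampling_rate) > 1e-9:
                raise ValueError("sampling_rate inconsistent with time grid")
        if self.reference_length <= 0:
            raise ValueError("reference_length must be positive")


@dataclass
class CycleBranch:
    """One monotone branch (loading or unloading) of a stress-strain cycle."""

    stress: np.ndarray  # MPa
    strain: np.ndarray  # %
    direction: str  # "loading" | "unloading"
    cycle_index: int  # 1-based


@dataclass
class CycleMetrics:
    cycle_index: int
    stiffness: float  # MPa
    normalized_hysteresis: float  # fraction
    peak_strain: float  # %


def compute_stress(load: np.ndarray, geometry: "SpecimenGeometry") -> np.ndarray:
    """Apparent stress in MPa from load in N (area in mm² so N/mm² = MPa)."""
    area = geometry.cross_section_area
    if area <= 0:
        raise ValueError("geometry has non-positive cross-section area")
    return np.asarray(load, dtype=float) / area


def compute_engineering_strain(displacement: np.ndarray, reference_length: float) -> np.ndarray:
    """Engineering strain in %, compression positive."""
    if reference_length <= 0:
        raise ValueError("reference_length must be positive")
    return 100.0 * np.asarray(displacement, dtype=float) / reference_length


def cycle_sample_bounds(
    stress: np.ndarray,
    sampling_rate: float,
    frequency: float,
    min_prominence_fraction: float = 0.25,
) -> list[tuple[int, int, int]]:
    """Sample indices (left_min, peak, right_min) of each complete
    min->max->min stress cycle.

    Peaks of the (load-controlled, hence clean) stress channel are located
    with a minimum spacing of 0.7 periods and a prominence of
    ``min_prominence_fraction`` of the overall stress range; cycle
    boundaries are the stress minima between consecutive peaks. A constant
    or non-periodic signal yields an empty list with a warning, not an
    exception.
    """
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    stress = np.asarray(stress, dtype=float)
    srange = float(np.ptp(stress))
    if srange <= 0:
        logger.warning("constant stress signal: no cycles found")
        return []
    distance = max(1, int(0.7 * sampling_rate / frequency))
    peaks, _ = find_peaks(stress, distance=distance, prominence=min_prominence_fraction * srange)
    if peaks.size == 0:
        logger.warning("no stress peaks found: signal appears non-periodic")
        return []
    period_n = max(2, int(round(sampling_rate / frequency)))
    # left boundary of the first cycle: stress minimum within one period
    # before the first peak (skips any preload plateau further back)
    lo = max(0, peaks[0] - period_n)
    bounds = [lo + int(np.argmin(stress[lo:peaks[0]]))]
    for a, b in zip(peaks[:-1], peaks[1:]):
        bounds.append(a + int(np.argmin(stress[a:b])))
    # right boundary after the final peak, if the signal comes back down
    tail = stress[peaks[-1]:]
    last_min = peaks[-1] + int(np.argmin(tail))
    complete_last = (
        last_min > peaks[-1]
        and stress[peaks[-1]] - stress[last_min] >= 0.5 * (stress[peaks[-1]] - stress[bounds[-1]])
    )
    if complete_last:
        bounds.append(last_min)
        use_peaks = peaks
    else:
        use_peaks = peaks[:-1]
    return [
        (bounds[k], int(p), bounds[k + 1]) for k, p in enumerate(use_peaks)
    ]


def segment_cycles(
    record: LoadDisplacementRecord,
    frequency: float,
    min_prominence_fraction: float = 0.25,
) -> list[tuple[CycleBranch, CycleBranch]]:
    """Split a record into complete min->max->min stress cycles.

    Cycles are delimited at stress minima (the test is load-controlled);
    only complete cycles are returned and indices are 1-based. A constant or
    non-periodic record yields an empty list with a warning.
    """
    stress = compute_stress(record.load, record.geometry)
    strain = compute_engineering_strain(record.displacement, record.reference_length)
    spans = cycle_sample_bounds(stress, record.sampling_rate, frequency, min_prominence_fraction)
    cycles: list[tuple[CycleBranch, CycleBranch]] = []
    for k, (left, p, right) in enumerate(spans, start=1):
        loading = CycleBranch(stress[left:p + 1], strain[left:p + 1], "loading", k)
        unloading = CycleBranch(stress[p:right + 1], strain[p:right + 1], "unloading", k)
        cycles.append((loading, unloading))
    return cycles


def stiffness_middle50(
    branch: CycleBranch,
    window: tuple[float, float] = (0.25, 0.75),
) -> float:
    """Apparent modulus (MPa): OLS slope of stress vs strain-as-fraction over
    samples whose stress lies in the central half of the branch stress range.

    The window is defined on the *stress* range (the controlled waveform) so
    the fit is load-level-defined and invariant to time resampling. The
    bounds are configurable for sensitivity analyses.
    """
    stress = np.asarray(branch.stress, dtype=float)
    strain_frac = np.asarray(branch.strain, dtype=float) / 100.0
    smin, smax = float(stress.min()), float(stress.max())
    if smax <= smin:
        raise ValueError(f"cycle {branch.cycle_index}: zero stress range")
    lo = smin + window[0] * (smax - smin)
    hi = smin + window[1] * (smax - smin)
    sel = (stress >= lo) & (stress <= hi)
    if int(sel.sum()) < 8:
        raise ValueError(
            f"cycle {branch.cycle_index}: only {int(sel.sum())} samples in the "
            f"middle-50% stress window (need >= 8)"
        )
    x = strain_frac[sel]
    y = stress[sel]
    if np.ptp(x) == 0:
        raise ValueError(f"cycle {branch.cycle_index}: zero strain variance in window")
    slope, _ = np.polyfit(x, y, 1)
    return float(slope)


def normalized_hysteresis(loading: CycleBranch, unloading: CycleBranch) -> float:
    """Fraction of loading work not returned during unloading.

    Work terms are trapezoid integrals of stress over strain along each
    branch's own strain span, so open loops (residual strain) count the
    unreturned deformation as dissipated energy.
    """
    if loading.cycle_index != unloading.cycle_index:
        raise ValueError("branches are from different cycles")
    el = np.asarray(loading.strain, dtype=float) / 100.0
    eu = np.asarray(unloading.strain, dtype=float) / 100.0
    w_load = float(np.trapezoid(np.asarray(loading.stress, float), el))
    if w_load <= 0:
        raise ValueError(f"cycle {loading.cycle_index}: non-positive loading work")
    # strain decreases along the unloading branch; the recovered work is the
    # magnitude of the (negative) signed integral
    w_unload = float(-np.trapezoid(np.asarray(unloading.stress, float), eu))
    return (w_load - w_unload) / w_load


def summarize_cycles(
    record: LoadDisplacementRecord,
    cycle_set: Sequence[int],
    frequency: float = 2.0,
) -> list[CycleMetrics]:
    """Stiffness, normalized hysteresis and peak strain at requested cycles."""
    cycles = segment_cycles(record, frequency)
    available = len(cycles)
    out = []
    for idx in cycle_set:
        if not 1 <= idx <= available:
            raise ValueError(
                f"cycle {idx} not available; record has complete cycles 1..{available}"
            )
        loading, unloading = cycles[idx - 1]
        out.append(
            CycleMetrics(
                cycle_index=idx,
                stiffness=stiffness_middle50(loading),
                normalized_hysteresis=normalized_hysteresis(loading, unloading),
                peak_strain=float(max(loading.strain.max(), unloading.strain.max())),
            )
        )
    return out
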
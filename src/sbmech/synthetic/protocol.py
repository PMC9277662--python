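"""Loading protocols and specimen geometry for synthetic cyclic-compression tests.

The study design loads cylindrical cartilage-bone specimens in unconfined
sinusoidal compression: dorsal MCIII specimens between 1 and 30 MPa, palmar
MCIII and proximal sesamoid specimens between 1 and 40 MPa, 100 cycles at
2 Hz, with load/displacement acquired at 500 Hz after a 20 N preload.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

SITES = ("dorsal", "palmar", "sesamoid")

#: (stress_min, stress_max) in MPa by collection site
SITE_STRESS_RANGE = {
    "dorsal": (1.0, 30.0),
    "palmar": (1.0, 40.0),
    "sesamoid": (1.0, 40.0),
}


@dataclass(frozen=True)
class LoadingProtocol:
    """Sinusoidal stress-controlled compression protocol.

    Stress in MPa, frequency and sampling rate in Hz, preload force in N,
    preload duration in s.
    """

    stress_min: float
    stress_max: float
    frequency: float = 2.0
    n_cycles: int = 100
    sampling_rate: float = 500.0
    preload_force: float = 20.0
    preload_duration: float = 300.0

    def __post_init__(self) -> None:
        if not self.stress_min < self.stress_max:
            raise ValueError(
                f"stress_min ({self.stress_min}) must be < stress_max ({self.stress_max})"
            )
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")
        if self.sampling_rate < 10 * self.frequency:
            raise ValueError(
                f"sampling_rate ({self.sampling_rate}) must be >= 10 x frequency "
                f"({self.frequency})"
            )
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")

    @property
    def stress_mean(self) -> float:
        return 0.5 * (self.stress_min + self.stress_max)

    @property
    def stress_amplitude(self) -> float:
        return 0.5 * (self.stress_max - self.stress_min)

    @property
    def period(self) -> float:
        return 1.0 / self.frequency


def make_protocol(site_label: str) -> LoadingProtocol:
    """Return the study loading protocol for a collection site.

    ``dorsal`` specimens run 1-30 MPa; ``palmar`` and ``sesamoid`` run
    1-40 MPa. All sites: 100 cycles at 2 Hz, 500 Hz acquisition, 20 N
    preload held for 5 min.
    """
    if site_label not in SITE_STRESS_RANGE:
        raise ValueError(
            f"unknown site label {site_label!r}; allowed: {sorted(SITE_STRESS_RANGE)}"
        )
    lo, hi = SITE_STRESS_RANGE[site_label]
    return LoadingProtocol(stress_min=lo, stress_max=hi)


@dataclass(frozen=True)
class SpecimenGeometry:
    """Cylindrical specimen with one flat vertical cut face.

    The flat cut (made so a speckled face can be imaged) removes the circular
    segment subtended by a chord of width ``flat_cut_chord``; the load-bearing
    cross-section is the circle area minus that segment. All lengths in mm.
    """

    diameter: float
    flat_cut_chord: float = 0.0
    height: float = 10.0
    cartilage_thickness: float = 0.56

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")
        if not 0 <= self.flat_cut_chord < self.diameter:
            raise ValueError("flat_cut_chord must satisfy 0 <= chord < diameter")
        if self.height <= 0:
            raise ValueError("height must be positive")
        if self.cartilage_thickness < 0:
            raise ValueError("cartilage_thickness must be >= 0")

    @property
    def cross_section_area(self) -> float:
        """Load-bearing cross-section in mm²."""
        r = 0.5 * self.diameter
        circle = math.pi * r * r
        if self.flat_cut_chord == 0:
            return circle
        half_chord = 0.5 * self.flat_cut_chord
        # distance from the cylinder axis to the cut plane
        apothem = math.sqrt(r * r - half_chord * half_chord)
        segment = r * r * math.acos(apothem / r) - apothem * half_chord
        return circle - segment
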
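"""Forward model of a layered viscoelastic specimen under sinusoidal
stress-controlled compression.

The specimen is a stack in series: an ordered list of bone layers
(superficial first) plus a "remainder" that lumps everything else
(non-mineralized cartilage and the bone outside the analysis layers). Each
layer is a spring with a rate-proportional (Kelvin-Voigt-style) dissipative
term whose phase lag is solved from the requested steady-state loop
energy-loss fraction at the protocol frequency, plus a residual strain that
accumulates by r * exp(-c * (k - 1)) over cycles k. Residual strain accrues
during the loading half of each cycle in proportion to the normalized stress,
which makes early cycles look more compliant and lets the apparent stiffness
rise monotonically toward the true modulus as accumulation dies out - the
"rapid, then more gradual" stiffening seen in cyclic compression of
cartilage-bone specimens.

For the loss-free, residual-free limit every loop closes reversibly and the
whole-specimen compliance is the thickness-weighted sum of layer compliances.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ..mechanics import LoadDisplacementRecord
from .protocol import LoadingProtocol, SpecimenGeometry


@dataclass(frozen=True)
class LayerMaterial:
    """One 1-D layer: elastic modulus (MPa), steady-state loop energy-loss
    fraction in [0, 1), and residual-strain accumulation rate/decay per cycle.
    """

    thickness: float  # mm
    modulus: float  # MPa
    loss_fraction: float = 0.0
    residual_strain_rate: float = 0.0  # strain per cycle at cycle 1
    residual_strain_decay: float = 0.5  # 1/cycle

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise ValueError("layer thickness must be positive")
        if self.modulus <= 0:
            raise ValueError("layer modulus must be positive")
        if not 0 <= self.loss_fraction < 1:
            raise ValueError("loss_fraction must be in [0, 1)")
        if self.residual_strain_rate < 0:
            raise ValueError("residual_strain_rate must be >= 0")
        if self.residual_strain_decay < 0:
            raise ValueError("residual_strain_decay must be >= 0")


@dataclass
class MechanicalTruth:
    """Generating values recorded alongside a simulated record."""

    layer_moduli: list[float]
    layer_loss_fractions: list[float]
    layer_thicknesses: list[float]
    remainder_modulus: float
    remainder_length: float
    whole_modulus: float  # series-compliance closed form, MPa
    layer_strain: dict[str, np.ndarray]  # fraction, per sample (cyclic part)
    remainder_strain: np.ndarray  # fraction, per sample
    residual_increments: dict[str, np.ndarray]  # per layer, per cycle
    preload_samples: int
    phase_lags: dict[str, float]  # rad
    time: np.ndarray = field(default=None)  # type: ignore[assignment]


def loss_phase_lag(loss_fraction: float, stress_mean: float, stress_amplitude: float) -> float:
    """Phase lag delta giving the requested normalized hysteresis.

    For stress sigma_m + sigma_a sin(theta) and strain lagging by delta, the
    branch-split normalized hysteresis (loading work minus unloading work over
    loading work, each over its own strain span) is

        H = pi sigma_a sin d / (2 sigma_m cos d + (pi/2) sigma_a sin d)

    which inverts to tan d = 2 H sigma_m / (pi sigma_a (1 - H/2)).
    """
    if loss_fraction == 0:
        return 0.0
    t = 2.0 * loss_fraction * stress_mean / (math.pi * stress_amplitude * (1.0 - loss_fraction / 2.0))
    return math.atan(t)


def series_modulus(
    layers: list[LayerMaterial], remainder_modulus: float, remainder_length: float, total_length: float
) -> float:
    """Whole-specimen modulus for springs in series (MPa)."""
    compliance = sum(l.thickness / total_length / l.modulus for l in layers)
    compliance += remainder_length / total_length / remainder_modulus
    return 1.0 / compliance


def _layer_strain_series(
    stress: np.ndarray,
    phase: np.ndarray,
    cycle_index: np.ndarray,
    in_cycle: np.ndarray,
    modulus: float,
    delta: float,
    resid_rate: float,
    resid_decay: float,
    sigma_a: float,
    omega_t: np.ndarray,
    n_cycles: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Strain (fraction) for one layer, plus its per-cycle residual increments.

    The viscoelastic part is sigma/E plus a quadrature term scaled so the
    in-phase strain amplitude is exactly sigma_a/E (the middle-50% slope of
    the loading branch then recovers E with only second-order bias).
    """
    strain = stress / modulus
    if delta > 0:
        quad = -(sigma_a * math.tan(delta) / modulus) * np.sin(omega_t)
        strain = strain + np.where(in_cycle, quad, 0.0)
    if resid_rate > 0:
        inc = resid_rate * np.exp(-resid_decay * (np.arange(1, n_cycles + 1) - 1))
        cum_before = np.concatenate([[0.0], np.cumsum(inc)[:-1]])
        # within-cycle accrual: proportional to normalized stress rise during
        # the loading half, held at the full increment during unloading
        p_load = 0.5 * (1.0 - np.cos(2.0 * math.pi * phase))
        p = np.where(phase < 0.5, p_load, 1.0)
        k = np.clip(cycle_index, 0, n_cycles - 1)
        resid = np.where(in_cycle, cum_before[k] + inc[k] * p, 0.0)
        strain = strain + resid
    else:
        inc = np.zeros(n_cycles)
    return strain, inc


def simulate_response(
    protocol: LoadingProtocol,
    geometry: SpecimenGeometry,
    layers: list[LayerMaterial],
    remainder_modulus: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    preload_record_s: float = 1.0,
    remainder_loss_fraction: float = 0.0,
    remainder_residual_rate: float = 0.0,
    remainder_residual_decay: float = 0.5,
) -> tuple[LoadDisplacementRecord, MechanicalTruth]:
    """Simulate a cyclic compression test of a layered specimen.

    Layers are ordered superficial -> deep. The emitted record carries a short
    preload plateau (``preload_record_s`` of the 5-min physical hold, which is
    steady state and carries no extra information), then the first quarter
    cycle ramps from the preload stress onto the sinusoid to avoid a stress
    discontinuity. Displacement is re-zeroed at the end of preload and
    Gaussian noise of sd ``noise_sd`` mm is added. All randomness flows from
    ``seed``.
    """
    if remainder_modulus <= 0:
        raise ValueError("remainder_modulus must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    layer_thickness = sum(l.thickness for l in layers)
    remainder_length = geometry.height - layer_thickness
    if remainder_length < 0:
        raise ValueError("layer thicknesses exceed specimen height")
    rng = np.random.default_rng(seed)

    fs = protocol.sampling_rate
    f = protocol.frequency
    n_pre = int(round(preload_record_s * fs))
    n_cyc = int(round(protocol.n_cycles * fs / f)) + 1  # include final minimum
    n = n_pre + n_cyc
    time = np.arange(n) / fs
    t_cyc = time - n_pre / fs  # cyclic-phase clock, <0 during preload

    area = geometry.cross_section_area
    sigma_p = protocol.preload_force / area
    sigma_m = protocol.stress_mean
    sigma_a = protocol.stress_amplitude
    omega = 2.0 * math.pi * f
    in_cycle = t_cyc >= 0
    tc = np.where(in_cycle, t_cyc, 0.0)
    sinusoid = sigma_m - sigma_a * np.cos(omega * tc)
    ramp_w = np.clip(tc / (0.25 / f), 0.0, 1.0)  # first quarter-cycle blend
    stress = np.where(in_cycle, (1 - ramp_w) * sigma_p + ramp_w * sinusoid, sigma_p)

    phase = np.mod(tc * f, 1.0)
    cycle_index = np.floor(tc * f).astype(int)  # 0-based, clipped later
    omega_t = omega * tc

    # simulated "remainder" behaves like one thick layer
    all_parts = list(layers) + [
        LayerMaterial(
            thickness=max(remainder_length, 1e-9),
            modulus=remainder_modulus,
            loss_fraction=remainder_loss_fraction,
            residual_strain_rate=remainder_residual_rate,
            residual_strain_decay=remainder_residual_decay,
        )
    ]
    names = [f"layer{i}" for i in range(len(layers))] + ["remainder"]

    strains: dict[str, np.ndarray] = {}
    incs: dict[str, np.ndarray] = {}
    lags: dict[str, float] = {}
    displacement = np.zeros(n)
    for name, part in zip(names, all_parts):
        delta = loss_phase_lag(part.loss_fraction, sigma_m, sigma_a)
        s, inc = _layer_strain_series(
            stress, phase, cycle_index, in_cycle, part.modulus, delta,
            part.residual_strain_rate, part.residual_strain_decay,
            sigma_a, omega_t, protocol.n_cycles,
        )
        strains[name] = s
        incs[name] = inc
        lags[name] = delta
        thickness = part.thickness if name != "remainder" else remainder_length
        displacement += s * thickness

    # re-zero at end of preload; reference length = specimen length then
    preload_comp = float(displacement[max(n_pre - 1, 0)])
    displacement = displacement - preload_comp
    reference_length = geometry.height - preload_comp
    if noise_sd > 0:
        displacement = displacement + rng.normal(0.0, noise_sd, size=n)

    record = LoadDisplacementRecord(
        time=time,
        load=stress * area,
        displacement=displacement,
        sampling_rate=fs,
        geometry=geometry,
        reference_length=reference_length,
    )
    truth = MechanicalTruth(
        layer_moduli=[l.modulus for l in layers],
        layer_loss_fractions=[l.loss_fraction for l in layers],
        layer_thicknesses=[l.thickness for l in layers],
        remainder_modulus=remainder_modulus,
        remainder_length=remainder_length,
        whole_modulus=series_modulus(layers, remainder_modulus, remainder_length, geometry.height),
        layer_strain={f"layer{i}": strains[f"layer{i}"] for i in range(len(layers))},
        remainder_strain=strains["remainder"],
        residual_increments=incs,
        preload_samples=n_pre,
        phase_lags=lags,
        time=time,
    )
    return record, truth
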
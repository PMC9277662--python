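"""Study configuration, the synthetic fixture study, and the end-to-end
pipeline: volumes -> morphometry, records -> cycle metrics, speckle frames ->
DIC layer strains, assembled into the long observation table that feeds the
descriptive and mixed-model statistics.

The fixture study emulates the design of the source experiment: 10 horses x
3 metacarpophalangeal sites (dorsal MCIII, palmar MCIII, proximal sesamoid),
each specimen a ~10 mm cartilage-bone cylinder with a superficial and a deep
2 mm subchondral layer. Site- and layer-level generating parameters are set
to the published descriptive means (deep stiffer than superficial
everywhere; dorsal least stiff and least dense; superficial hysteresis
higher at palmar/sesamoid), with horse-level and specimen-level lognormal
variation, so fitted site/layer effects have known signs and magnitudes.

Imaging and volume problem sizes are scaled to desk hardware (coarser voxels
and a camera-memory-limited number of frames per analyzed cycle); the scale
parameters live in StudyConfig and are stated in the methods note.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import dic as dic_mod
from . import io as io_mod
from . import mechanics as mech
from . import morphometry as morph
from . import stats as stats_mod
from .synthetic import (
    LayerMaterial,
    SpecimenGeometry,
    generate_volume,
    make_protocol,
    make_speckle_image,
    render_speckle_sequence,
    simulate_response,
)

logger = logging.getLogger(__name__)

SITES = ("dorsal", "palmar", "sesamoid")

#: Site-level generating means. Layer moduli and loss fractions sit at the
#: published first-cycle descriptive means; remainder moduli are solved so
#: the whole-specimen series stiffness lands at the published totals.
SITE_TRUTH = {
    #        E_sup, E_deep,  H_sup, H_deep, E_rem,  bvtv, bvtv_grad, bmd, bmd_grad, dmg
    "dorsal": dict(e_sup=4345.0, e_deep=6063.0, h_sup=0.29, h_deep=0.12,
                   e_rem=1572.0, bvtv=0.71, bvtv_grad=-0.060, bmd=891.0,
                   bmd_grad=21.3, damage=0.03),
    "palmar": dict(e_sup=5059.0, e_deep=8644.0, h_sup=0.36, h_deep=0.18,
                   e_rem=2224.0, bvtv=0.87, bvtv_grad=-0.015, bmd=913.0,
                   bmd_grad=19.8, damage=0.02),
    "sesamoid": dict(e_sup=4890.0, e_deep=9289.0, h_sup=0.38, h_deep=0.12,
                     e_rem=1967.0, bvtv=0.83, bvtv_grad=-0.045, bmd=928.0,
                     bmd_grad=19.5, damage=0.04),
}

#: residual-strain accumulation: small in the bone layers (their stiffness
#: barely changes over cycles 1-9), larger in the cartilage-dominated
#: remainder (the whole specimen stiffens ~10 % over 100 cycles)
LAYER_RESIDUAL_RATE = 1.0e-4
LAYER_RESIDUAL_DECAY = 0.5
REMAINDER_RESIDUAL_RATE = 2.5e-3
REMAINDER_RESIDUAL_DECAY = 0.35
REMAINDER_LOSS = 0.30

HORSE_SD = 0.12  # lognormal sd of the horse-level modulus multiplier
SPECIMEN_SD = 0.10  # lognormal sd of the specimen-level multiplier


@dataclass
class SpecimenRecord:
    """Metadata carried per specimen (grades are 0/1 eyeball inputs)."""

    specimen_id: str
    horse_id: str
    site: str
    age: float
    sex: str  # female | male_entire | male_gelded
    limb: str  # left | right
    pod_grade: int
    microfracture: int
    resorption: int
    fracture_death: int
    geometry: SpecimenGeometry


@dataclass
class SpecimenPlan:
    """Generating parameters and seeds for one synthetic specimen."""

    meta: SpecimenRecord
    e_sup: float
    e_deep: float
    h_sup: float
    h_deep: float
    e_rem: float
    target_bvtv: float
    bvtv_grad: float
    tissue_bmd: float
    bmd_grad: float
    damage_fraction: float
    seed_record: int
    seed_volume: int
    seed_speckle: int


@dataclass
class StudyConfig:
    """Everything needed to (re)run a study deterministically."""

    seed: int
    specimens: list[SpecimenPlan]
    # mechanics
    noise_sd_mm: float = 5.0e-4
    preload_record_s: float = 1.0
    total_cycles: tuple[int, ...] = mech.TOTAL_CYCLES
    layer_cycles: tuple[int, ...] = mech.LAYER_CYCLES
    # volumes (scaled problem size)
    volume_shape: tuple[int, int, int] = (110, 96, 96)
    voxel_size_um: float = 60.0
    # DIC imaging
    pixel_size_mm: float = 0.03
    image_shape: tuple[int, int] = (224, 200)
    frames_per_cycle: int = 32
    subset_size: int = 31
    subset_step: int = 8
    search_radius: int = 8
    score_threshold: float = 0.6
    video_offset_s: float = 0.01
    # morphometry thresholds
    upper_threshold: float = morph.UPPER_THRESHOLD_DEFAULT
    label_threshold: float = morph.LABEL_THRESHOLD_DEFAULT
    edge_margin_mm: float = 1.0
    # output
    out_dir: str | None = None
    write_raw: bool = False


@dataclass
class StudyResult:
    layer_table: pd.DataFrame
    total_table: pd.DataFrame
    descriptives: dict[str, pd.DataFrame]
    collinearity: list[tuple[str, str, float]]
    fits: dict[str, stats_mod.FitResult]
    truth: pd.DataFrame  # per-specimen generating values
    failures: list[tuple[str, str, str]]  # (specimen, stage, message)
    manifest: dict


def save_config(config: StudyConfig, path: str | Path) -> None:
    """Write the full study configuration as a declarative YAML file."""
    import yaml

    payload = asdict(config)
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_config(path: str | Path) -> StudyConfig:
    """Read a study configuration written by :func:`save_config`."""
    import yaml

    payload = yaml.safe_load(Path(path).read_text())
    specimens = []
    for p in payload.pop("specimens"):
        meta = p.pop("meta")
        geometry = SpecimenGeometry(**meta.pop("geometry"))
        specimens.append(SpecimenPlan(meta=SpecimenRecord(geometry=geometry, **meta), **p))
    for key in ("total_cycles", "layer_cycles", "volume_shape", "image_shape"):
        payload[key] = tuple(payload[key])
    return StudyConfig(specimens=specimens, **payload)


def make_fixture_study(seed: int, n_horses: int = 10, **overrides) -> StudyConfig:
    """Draw a 3-sites-per-horse study plan with known ground truth."""
    if n_horses < 2:
        raise ValueError("need at least 2 horses")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xFC]))
    plans: list[SpecimenPlan] = []
    sexes = ["female", "male_entire", "male_gelded"]
    # one palmar specimen carries a microfracture, as observed in the study
    mf_horse = int(rng.integers(n_horses))
    for h in range(n_horses):
        horse_id = f"H{h + 1:02d}"
        age = float(np.clip(rng.normal(3.66, 0.42), 2.5, 5.0))
        sex = sexes[int(rng.integers(3))]
        limb = "left" if rng.random() < 0.3 else "right"
        horse_mult = float(rng.lognormal(0.0, HORSE_SD))
        fracture_death = int(rng.random() < 0.5)
        for site in SITES:
            truth = SITE_TRUTH[site]
            spec_mult = float(rng.lognormal(0.0, SPECIMEN_SD))
            mult = horse_mult * spec_mult
            geometry = SpecimenGeometry(
                diameter=float(rng.normal(6.66, 0.05)),
                flat_cut_chord=float(rng.normal(4.95, 0.19)),
                height=float(rng.normal(10.12, 0.37)),
                cartilage_thickness=float(np.clip(rng.normal(0.56, 0.09), 0.2, 1.0)),
            )
            meta = SpecimenRecord(
                specimen_id=f"{horse_id}-{site}",
                horse_id=horse_id,
                site=site,
                age=age,
                sex=sex,
                limb=limb,
                pod_grade=int(rng.random() < 0.3),
                microfracture=int(site == "palmar" and h == mf_horse),
                resorption=int(rng.random() < 0.2),
                fracture_death=fracture_death,
                geometry=geometry,
            )
            sub = np.random.SeedSequence([seed, h, SITES.index(site)])
            s_rec, s_vol, s_spk = [int(s.generate_state(1)[0] % (2**31)) for s in sub.spawn(3)]
            plans.append(
                SpecimenPlan(
                    meta=meta,
                    e_sup=truth["e_sup"] * mult,
                    e_deep=truth["e_deep"] * mult,
                    h_sup=float(np.clip(truth["h_sup"] * rng.lognormal(0, 0.10), 0.02, 0.6)),
                    h_deep=float(np.clip(truth["h_deep"] * rng.lognormal(0, 0.10), 0.02, 0.6)),
                    e_rem=truth["e_rem"] * mult,
                    target_bvtv=float(np.clip(truth["bvtv"] * rng.lognormal(0, 0.06), 0.3, 0.97)),
                    bvtv_grad=truth["bvtv_grad"],
                    tissue_bmd=float(rng.normal(truth["bmd"], 20.0)),
                    bmd_grad=truth["bmd_grad"],
                    damage_fraction=float(np.clip(rng.normal(truth["damage"], 0.008), 0.0, 0.15)),
                    seed_record=s_rec,
                    seed_volume=s_vol,
                    seed_speckle=s_spk,
                )
            )
    return StudyConfig(seed=seed, specimens=plans, **overrides)


def _layers_for(plan: SpecimenPlan) -> list[LayerMaterial]:
    return [
        LayerMaterial(2.0, plan.e_sup, plan.h_sup, LAYER_RESIDUAL_RATE, LAYER_RESIDUAL_DECAY),
        LayerMaterial(2.0, plan.e_deep, plan.h_deep, LAYER_RESIDUAL_RATE, LAYER_RESIDUAL_DECAY),
    ]


def simulate_specimen_record(plan: SpecimenPlan, config: StudyConfig):
    """Forward-simulate one specimen's load-displacement record."""
    protocol = make_protocol(plan.meta.site)
    return simulate_response(
        protocol,
        plan.meta.geometry,
        _layers_for(plan),
        remainder_modulus=plan.e_rem,
        noise_sd=config.noise_sd_mm,
        seed=plan.seed_record,
        preload_record_s=config.preload_record_s,
        remainder_loss_fraction=REMAINDER_LOSS,
        remainder_residual_rate=REMAINDER_RESIDUAL_RATE,
        remainder_residual_decay=REMAINDER_RESIDUAL_DECAY,
    )


def _windowed_slope(stress: np.ndarray, strain_pct: np.ndarray,
                    window: tuple[float, float] = (0.25, 0.75), min_samples: int = 5) -> float:
    """OLS stiffness (MPa) on sparse frame samples, windowed on stress range."""
    smin, smax = float(stress.min()), float(stress.max())
    lo = smin + window[0] * (smax - smin)
    hi = smin + window[1] * (smax - smin)
    sel = (stress >= lo) & (stress <= hi)
    if int(sel.sum()) < min_samples:
        raise ValueError(f"only {int(sel.sum())} frames in the stiffness window")
    return float(np.polyfit(strain_pct[sel] / 100.0, stress[sel], 1)[0])


def _loop_metrics(stress: np.ndarray, strain_pct: np.ndarray) -> tuple[float, float, float]:
    """(stiffness, hysteresis, peak strain) for one cycle's frame samples.

    Stiffness is fitted on the loading branch only (frames up to the stress
    peak), mirroring the record-level middle-50% estimator.
    """
    peak = int(np.argmax(stress))
    e = strain_pct / 100.0
    w_load = float(np.trapezoid(stress[:peak + 1], e[:peak + 1]))
    w_unload = float(-np.trapezoid(stress[peak:], e[peak:]))
    hyst = (w_load - w_unload) / w_load if w_load > 0 else np.nan
    stiff = _windowed_slope(stress[:peak + 1], strain_pct[:peak + 1])
    return stiff, hyst, float(strain_pct.max())


def layer_metrics_from_truth(record, truth, cycles, frequency: float = 2.0) -> pd.DataFrame:
    """Per-cycle layer stiffness/hysteresis straight from the simulator's
    layer strain channels (a virtual extensometer; used for statistical
    replicate studies, where re-rendering and re-correlating speckle frames
    per replicate would add nothing but runtime)."""
    stress = mech.compute_stress(record.load, record.geometry)
    spans = mech.cycle_sample_bounds(stress, record.sampling_rate, frequency)
    rows = []
    n_pre = truth.preload_samples
    for layer_name, key in (("superficial", "layer0"), ("deep", "layer1")):
        strain = (truth.layer_strain[key] - truth.layer_strain[key][n_pre - 1]) * 100.0
        for k in cycles:
            left, peak, right = spans[k - 1]
            loading = mech.CycleBranch(stress[left:peak + 1], strain[left:peak + 1], "loading", k)
            unloading = mech.CycleBranch(stress[peak:right + 1], strain[peak:right + 1], "unloading", k)
            rows.append(dict(
                layer=layer_name,
                cycle=k,
                stiffness_MPa=mech.stiffness_middle50(loading),
                hysteresis_fraction=mech.normalized_hysteresis(loading, unloading),
                peak_strain_pct=float(max(loading.strain.max(), unloading.strain.max())),
            ))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# imaging stage


def _strain_profile_rows(plan: SpecimenPlan, config: StudyConfig,
                         eps_sup, eps_deep, eps_rem, surface_row: float):
    """Axial pixel displacement v(row) for the specimen face: the base is
    fixed, so a point at depth d moves down by the compression of the
    material below it, v(d) = total - integral_0^d eps dz."""
    n_rows, _ = config.image_shape
    px = config.pixel_size_mm
    geo = plan.meta.geometry
    cart = geo.cartilage_thickness
    depths = (np.arange(n_rows) - surface_row) * px  # mm below cartilage surface
    eps = np.full(n_rows, eps_rem, dtype=float)
    iface = cart
    sup_lo, sup_hi = iface + 0.5, iface + 2.5
    deep_hi = iface + 4.5
    eps[(depths >= sup_lo) & (depths < sup_hi)] = eps_sup
    eps[(depths >= sup_hi) & (depths < deep_hi)] = eps_deep
    eps[depths < 0] = 0.0  # background above the specimen
    total_mm = eps_rem * (geo.height - 4.0) + (eps_sup + eps_deep) * 2.0
    cum = np.cumsum(np.where(depths >= 0, eps, 0.0)) * px
    v_mm = total_mm - cum
    v_mm[depths < 0] = total_mm  # platen side moves with the surface
    return v_mm / px  # px, positive downward


def render_specimen_frames(plan: SpecimenPlan, config: StudyConfig, record, truth):
    """Speckle frames at ``frames_per_cycle`` evenly spaced instants within
    each analyzed cycle (the camera-memory-limited subsample of 500 fps).

    Returns (frames, frame_times, surface_row, interface_row).
    """
    fs = record.sampling_rate
    n_pre = truth.preload_samples
    period = 1.0 / 2.0
    surface_row = 12.0
    interface_row = surface_row + plan.meta.geometry.cartilage_thickness / config.pixel_size_mm
    ref = make_speckle_image(config.image_shape, seed=plan.seed_speckle)
    strains = {}
    for key, arr in (("sup", truth.layer_strain["layer0"]),
                     ("deep", truth.layer_strain["layer1"]),
                     ("rem", truth.remainder_strain)):
        strains[key] = arr - arr[n_pre - 1]
    frame_times = []
    fields = []
    n_rows, n_cols = config.image_shape
    for k in config.layer_cycles:
        for j in range(config.frames_per_cycle):
            t = (n_pre / fs) + (k - 1) * period + (j + 0.5) / config.frames_per_cycle * period
            i = int(round(t * fs))
            v_rows = _strain_profile_rows(
                plan, config, strains["sup"][i], strains["deep"][i], strains["rem"][i],
                surface_row,
            )
            v = np.broadcast_to(v_rows[:, None], (n_rows, n_cols)).copy()
            fields.append((np.zeros((n_rows, n_cols)), v))
            frame_times.append(t)
    frames, _ = render_speckle_sequence(fields, reference=ref)
    return frames, np.array(frame_times), surface_row, interface_row


def dic_layer_metrics(plan: SpecimenPlan, config: StudyConfig, record, truth) -> pd.DataFrame:
    """Track speckle frames, extract per-frame layer strains, synchronize to
    the load record, and summarize per analyzed cycle and layer."""
    frames, frame_times, surface_row, interface_row = render_specimen_frames(
        plan, config, record, truth
    )
    ref = frames[0]
    # sample bands inset from the layer bounds by the subset radius so every
    # correlation window sees only in-layer material (strain is uniform
    # within a layer, so the inset gauge measures the same layer strain
    # while avoiding the displacement kinks at the bound depths)
    inset = (config.subset_size // 2) * config.pixel_size_mm
    sup_bounds = dic_mod.LayerBounds(
        dic_mod.SUPERFICIAL_BOUNDS.upper_bound_depth + inset,
        dic_mod.SUPERFICIAL_BOUNDS.lower_bound_depth - inset,
    )
    deep_bounds = dic_mod.LayerBounds(
        dic_mod.DEEP_BOUNDS.upper_bound_depth + inset,
        dic_mod.DEEP_BOUNDS.lower_bound_depth - inset,
    )
    band_rows = []
    for depth in (sup_bounds.upper_bound_depth, sup_bounds.lower_bound_depth,
                  deep_bounds.upper_bound_depth, deep_bounds.lower_bound_depth):
        band_rows.append(int(round(interface_row + depth / config.pixel_size_mm)))
    rows = np.unique(band_rows)
    sup_strain, deep_strain = [], []
    prev = None
    for f in frames[1:]:
        field = dic_mod.track_subsets(
            ref, f,
            subset_size=config.subset_size,
            step=config.subset_step,
            search_radius=config.search_radius,
            score_threshold=config.score_threshold,
            rows=rows,
            subpixel="gauss_newton",
            initial=prev,
        )
        prev = field
        sup_strain.append(dic_mod.layer_strain(
            field, sup_bounds, config.pixel_size_mm, interface_row,
            band_half_width_px=config.subset_step // 2,
        ))
        deep_strain.append(dic_mod.layer_strain(
            field, deep_bounds, config.pixel_size_mm, interface_row,
            band_half_width_px=config.subset_step // 2,
        ))
    # video-clock actuator displacement: the record's channel sampled at the
    # frame instants, shifted by the (unknown to the analysis) video offset
    video_times = frame_times - config.video_offset_s
    video_disp = np.interp(frame_times, record.time, record.displacement)
    out = []
    for layer_name, strain in (("superficial", np.array(sup_strain)),
                               ("deep", np.array(deep_strain))):
        series = dic_mod.synchronize(
            strain, video_disp, video_times, record,
            cycles=tuple(config.layer_cycles), layer=layer_name,
        )
        for k in config.layer_cycles:
            sel = series.cycle_index == k
            if int(sel.sum()) < 6:
                raise ValueError(f"cycle {k}: too few synchronized frames")
            stiff, hyst, peak = _loop_metrics(series.stress[sel], series.strain[sel])
            out.append(dict(layer=layer_name, cycle=k, stiffness_MPa=stiff,
                            hysteresis_fraction=hyst, peak_strain_pct=peak))
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# morphometry stage


def specimen_morphometry(plan: SpecimenPlan, config: StudyConfig) -> dict:
    """Generate the specimen's (stained) volume and run the full
    morphometry chain; returns per-layer metrics plus surface geometry."""
    volume, vtruth = generate_volume(
        shape=config.volume_shape,
        voxel_size=config.voxel_size_um,
        target_bvtv=plan.target_bvtv,
        tissue_bmd=plan.tissue_bmd,
        bmd_depth_gradient=plan.bmd_grad,
        damage_fraction=plan.damage_fraction,
        seed=plan.seed_volume,
        bvtv_depth_gradient=plan.bvtv_grad,
        cartilage_thickness_mm=plan.meta.geometry.cartilage_thickness,
    )
    vox_mm = volume.voxel_size_mm
    cal = morph.calibrate_density(
        volume,
        (vtruth.phantoms[0].mask, vtruth.phantoms[1].mask),
        (vtruth.phantoms[0].density, vtruth.phantoms[1].density),
    )
    lower = morph.default_lower_threshold(volume, vtruth.specimen_footprint)
    mask = morph.smooth_and_segment(volume, lower, config.upper_threshold)
    mask &= vtruth.specimen_footprint[None, :, :]
    _, iface_ref = morph.detect_interface(mask, vox_mm, footprint=vtruth.specimen_footprint)
    iface_map, _ = morph.detect_interface(mask, vox_mm, footprint=vtruth.specimen_footprint)
    specs = [
        morph.RoiSpec("superficial", 0.5, 2.0, config.edge_margin_mm),
        morph.RoiSpec("deep", 2.5, 2.0, config.edge_margin_mm),
        morph.RoiSpec("total", 0.0, 0.0, config.edge_margin_mm),
    ]
    rois = morph.build_rois(volume.data.shape, iface_ref, specs, vox_mm,
                            vtruth.specimen_footprint)
    per_layer = {}
    for layer_name in ("superficial", "deep", "total"):
        roi = rois[layer_name]
        bvtv, bmd = morph.compute_bvtv_bmd(volume, mask, roi, cal)
        if layer_name == "total":
            bsa = float("nan")
            dbv = dbvf = adj = float("nan")
        else:
            bsa = morph.compute_bsa(mask, roi, vox_mm)
            dbv, dbvf, adj = morph.quantify_damage(
                volume, mask, roi, vox_mm,
                label_threshold=config.label_threshold, bsa=bsa,
            )
        per_layer[layer_name] = dict(
            bvtv=bvtv, bmd=bmd, bsa_mm2=bsa, dbv_mm3=dbv, dbvf=dbvf, adjusted_dbv=adj,
        )
    cart_map = morph.detect_cartilage_surface(volume, vtruth.specimen_footprint)
    surface = morph.surface_geometry(
        iface_map, cart_map, vtruth.specimen_footprint, vox_mm
    )
    return dict(per_layer=per_layer, surface=surface, truth=vtruth, calibration=cal)


# ---------------------------------------------------------------------------
# the end-to-end run


def _meta_columns(plan: SpecimenPlan, surface: morph.SurfaceMetrics | None) -> dict:
    m = plan.meta
    d = dict(
        specimen_id=m.specimen_id, horse_id=m.horse_id, site=m.site, age=m.age,
        sex=m.sex, limb=m.limb, pod_grade=m.pod_grade, microfracture=m.microfracture,
        resorption=m.resorption, fracture_death=m.fracture_death,
        cartilage_thickness_mm=m.geometry.cartilage_thickness,
    )
    if surface is not None:
        d.update(
            angle_a=surface.surface_angle_a, angle_b=surface.surface_angle_b,
            evenness_a=surface.evenness_area_a, evenness_b=surface.evenness_area_b,
        )
    return d


def run_pipeline(config: StudyConfig, skip_imaging: bool = False,
                 skip_volumes: bool = False) -> StudyResult:
    """Execute morphometry, mechanics, DIC and statistics for every
    specimen. Stage failures are logged with specimen and stage and the run
    continues; the failure list rides along in the result. ``skip_imaging``
    replaces the DIC stage with the virtual-extensometer layer metrics and
    ``skip_volumes`` drops morphometry columns (both used by replicate
    studies and quick looks)."""
    layer_rows, total_rows, truth_rows = [], [], []
    failures: list[tuple[str, str, str]] = []
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    for plan in config.specimens:
        sid = plan.meta.specimen_id
        try:
            record, mtruth = simulate_specimen_record(plan, config)
        except Exception as exc:  # noqa: BLE001 - stage isolation by design
            logger.error("%s: simulation failed: %s", sid, exc)
            failures.append((sid, "simulate", str(exc)))
            continue

        morph_data = None
        if not skip_volumes:
            try:
                morph_data = specimen_morphometry(plan, config)
            except Exception as exc:  # noqa: BLE001
                logger.error("%s: morphometry failed: %s", sid, exc)
                failures.append((sid, "morphometry", str(exc)))

        try:
            totals = mech.summarize_cycles(record, config.total_cycles)
        except Exception as exc:  # noqa: BLE001
            logger.error("%s: mechanics failed: %s", sid, exc)
            failures.append((sid, "mechanics", str(exc)))
            totals = []

        try:
            if skip_imaging:
                layer_df = layer_metrics_from_truth(record, mtruth, config.layer_cycles)
            else:
                layer_df = dic_layer_metrics(plan, config, record, mtruth)
        except Exception as exc:  # noqa: BLE001
            logger.error("%s: DIC failed: %s", sid, exc)
            failures.append((sid, "dic", str(exc)))
            layer_df = pd.DataFrame()

        surface = morph_data["surface"] if morph_data else None
        meta_cols = _meta_columns(plan, surface)
        for cm in totals:
            row = dict(meta_cols)
            row.update(layer="total", cycle=cm.cycle_index,
                       stiffness_MPa=cm.stiffness,
                       hysteresis_fraction=cm.normalized_hysteresis,
                       peak_strain_pct=cm.peak_strain)
            if morph_data:
                row.update({k: v for k, v in morph_data["per_layer"]["total"].items()})
            total_rows.append(row)
        for _, lr in layer_df.iterrows():
            row = dict(meta_cols)
            row.update(lr.to_dict())
            if morph_data:
                row.update({k: v for k, v in morph_data["per_layer"][lr["layer"]].items()})
            layer_rows.append(row)
        truth_rows.append(dict(
            specimen_id=sid, horse_id=plan.meta.horse_id, site=plan.meta.site,
            e_sup=plan.e_sup, e_deep=plan.e_deep, e_rem=plan.e_rem,
            h_sup=plan.h_sup, h_deep=plan.h_deep,
            whole_modulus=mtruth.whole_modulus,
            target_bvtv=plan.target_bvtv, tissue_bmd=plan.tissue_bmd,
            damage_fraction=plan.damage_fraction,
            bvtv_truth=(morph_data["truth"].bvtv if morph_data else np.nan),
            bmd_truth=(morph_data["truth"].mean_tissue_bmd if morph_data else np.nan),
            damage_truth=(morph_data["truth"].damage_fraction if morph_data else np.nan),
        ))

    layer_table = pd.DataFrame(layer_rows)
    total_table = pd.DataFrame(total_rows)
    truth_table = pd.DataFrame(truth_rows)

    desc: dict[str, pd.DataFrame] = {}
    fits: dict[str, stats_mod.FitResult] = {}
    screen: list[tuple[str, str, float]] = []
    try:
        if not layer_table.empty:
            first = layer_table[layer_table["cycle"] == 1]
            for outcome in ("stiffness_MPa", "hysteresis_fraction", "peak_strain_pct"):
                desc[f"layer_{outcome}"] = stats_mod.descriptives(first, outcome)
        if not total_table.empty:
            first_t = total_table[total_table["cycle"] == 1]
            for outcome in ("stiffness_MPa", "hysteresis_fraction", "peak_strain_pct"):
                desc[f"total_{outcome}"] = stats_mod.descriptives(first_t, outcome)
            numeric = [c for c in ("bvtv", "bmd", "age", "cartilage_thickness_mm",
                                   "angle_a", "angle_b", "evenness_a", "evenness_b")
                       if c in total_table.columns]
            if numeric:
                screen = stats_mod.collinearity_screen(
                    first_t.drop_duplicates("specimen_id"), numeric
                )
        if not layer_table.empty and layer_table["horse_id"].nunique() >= 2:
            fits["layer_stiffness"] = stats_mod.fit_mixed(
                stats_mod.ModelSpec("stiffness_MPa", ["layer", "site", "C(cycle)"]),
                layer_table,
            )
            fits["layer_hysteresis"] = stats_mod.fit_mixed(
                stats_mod.ModelSpec("hysteresis_fraction", ["layer", "site", "C(cycle)"]),
                layer_table,
            )
        if not total_table.empty and total_table["horse_id"].nunique() >= 2:
            fits["total_stiffness"] = stats_mod.fit_mixed(
                stats_mod.ModelSpec("stiffness_MPa", ["site", "C(cycle)"]),
                total_table,
            )
    except Exception as exc:  # noqa: BLE001
        logger.error("statistics stage failed: %s", exc)
        failures.append(("*", "statistics", str(exc)))

    manifest = dict(
        seed=config.seed,
        n_specimens=len(config.specimens),
        config_hash=config_hash(config),
        n_layer_rows=len(layer_table),
        n_total_rows=len(total_table),
        failures=failures,
    )
    if out_dir:
        layer_table.to_csv(out_dir / "layer_table.csv", index=False)
        total_table.to_csv(out_dir / "total_table.csv", index=False)
        truth_table.to_csv(out_dir / "truth_table.csv", index=False)
        io_mod.write_json(out_dir / "manifest.json", manifest)
    return StudyResult(
        layer_table=layer_table,
        total_table=total_table,
        descriptives=desc,
        collinearity=screen,
        fits=fits,
        truth=truth_table,
        failures=failures,
        manifest=manifest,
    )


def mechanics_tables(config: StudyConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Layer and total cycle-metric tables from records alone (virtual
    extensometer for the layers; no imaging, no volumes). Used by replicate
    studies of the statistical workflow."""
    layer_rows, total_rows = [], []
    for plan in config.specimens:
        record, truth = simulate_specimen_record(plan, config)
        base = dict(specimen_id=plan.meta.specimen_id, horse_id=plan.meta.horse_id,
                    site=plan.meta.site)
        for cm in mech.summarize_cycles(record, config.total_cycles):
            total_rows.append(dict(base, layer="total", cycle=cm.cycle_index,
                                   stiffness_MPa=cm.stiffness,
                                   hysteresis_fraction=cm.normalized_hysteresis))
        ldf = layer_metrics_from_truth(record, truth, config.layer_cycles)
        for _, lr in ldf.iterrows():
            total = dict(base)
            total.update(lr.to_dict())
            layer_rows.append(total)
    return pd.DataFrame(layer_rows), pd.DataFrame(total_rows)


def replicate_sign_study(seed: int, n_replicates: int = 50, n_horses: int = 10) -> pd.DataFrame:
    """Fit the layer/site mixed models on ``n_replicates`` fresh synthetic
    studies and record whether each fixed effect carries its generating sign
    (deep stiffer than superficial; dorsal least stiff; superficial more
    dissipative).

    Returns one row per replicate with boolean sign indicators.
    """
    out = []
    for r in range(n_replicates):
        rep_seed = int(np.random.SeedSequence([seed, r]).generate_state(1)[0] % (2**31))
        cfg = make_fixture_study(rep_seed, n_horses=n_horses)
        layer_table, total_table = mechanics_tables(cfg)
        stiff = stats_mod.fit_mixed(
            stats_mod.ModelSpec("stiffness_MPa", ["layer", "site", "C(cycle)"]), layer_table
        )
        hyst = stats_mod.fit_mixed(
            stats_mod.ModelSpec("hysteresis_fraction", ["layer", "site", "C(cycle)"]), layer_table
        )
        total = stats_mod.fit_mixed(
            stats_mod.ModelSpec("stiffness_MPa", ["site", "C(cycle)"]), total_table
        )
        out.append(dict(
            replicate=r,
            layer_sign=stiff.params["layer[T.superficial]"] < 0,
            site_palmar_sign=stiff.params["site[T.palmar]"] > 0,
            site_sesamoid_sign=stiff.params["site[T.sesamoid]"] > 0,
            hyst_layer_sign=hyst.params["layer[T.superficial]"] > 0,
            total_palmar_sign=total.params["site[T.palmar]"] > 0,
            total_sesamoid_sign=total.params["site[T.sesamoid]"] > 0,
        ))
    return pd.DataFrame(out)


def config_hash(config: StudyConfig) -> str:
    """Stable hash of the full configuration (for the run manifest)."""

    def enc(o):
        if isinstance(o, (SpecimenPlan, SpecimenRecord, SpecimenGeometry)):
            return asdict(o)
        if isinstance(o, Path):
            return str(o)
        raise TypeError(str(type(o)))

    payload = json.dumps(asdict(config), sort_keys=True, default=enc)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_fixture_files(config: StudyConfig, out_dir: str | Path) -> None:
    """Write the raw synthetic inputs (records as CSV, one volume stack +
    sidecar per specimen, speckle frames for the first specimen) so the file
    formats round-trip; deterministic given the config."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for i, plan in enumerate(config.specimens):
        sdir = out_dir / plan.meta.specimen_id
        sdir.mkdir(exist_ok=True)
        record, mtruth = simulate_specimen_record(plan, config)
        io_mod.write_record_csv(sdir / "record.csv", record)
        volume, vtruth = generate_volume(
            shape=config.volume_shape, voxel_size=config.voxel_size_um,
            target_bvtv=plan.target_bvtv, tissue_bmd=plan.tissue_bmd,
            bmd_depth_gradient=plan.bmd_grad, damage_fraction=plan.damage_fraction,
            seed=plan.seed_volume, bvtv_depth_gradient=plan.bvtv_grad,
            cartilage_thickness_mm=plan.meta.geometry.cartilage_thickness,
        )
        io_mod.write_volume(sdir / "volume.tif", volume, sidecar=dict(
            bvtv_truth=vtruth.bvtv, bmd_truth=vtruth.mean_tissue_bmd,
            damage_truth=vtruth.damage_fraction,
            phantom_densities=[p.density for p in vtruth.phantoms],
            phantom_centers=[list(p.center_yx) for p in vtruth.phantoms],
        ))
        if i == 0:
            frames, frame_times, *_ = render_specimen_frames(plan, config, record, mtruth)
            io_mod.write_frames(sdir / "frames", frames[: 1 + config.frames_per_cycle])
    io_mod.write_json(out_dir / "config.json", dict(seed=config.seed, hash=config_hash(config)))
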
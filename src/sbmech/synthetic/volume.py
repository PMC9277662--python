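"""Synthetic microCT-like voxel volumes with known morphometric ground truth.

A cylindrical trabecular "specimen" (threshold of a smoothed Gaussian random
field, so structures are connected and smooth at the few-voxel scale) sits in
a saline background together with two homogeneous calcium-hydroxyapatite
calibration phantom rods in the volume corners. Grayscale is an affine image
of mineral density - gs = GS_PER_DENSITY * density(mg HA/ccm) plus mild
noise - chosen so that the conventional segmentation numbers are meaningful:
bone tissue at ~900 mg HA/ccm sits near gs 405, between a lower threshold of
a few hundred and the 550 label threshold, while lead-uranyl "damage" labels
are rendered above 550 and nothing approaches the 1000 upper threshold.

Ground truth (realized bone volume fraction, mean tissue density, damage
counts and the exact masks) is recorded by direct voxel counting on the
emitted arrays.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_erosion, gaussian_filter

#: grayscale units per mg HA/ccm (documented affine convention, intercept 0)
GS_PER_DENSITY = 0.45
#: grayscale assigned to labeled ("damaged") voxels, above the 550 threshold
LABEL_GS = 650.0
#: density given to the non-mineralized cartilage cap (mg HA/ccm): faint but
#: above saline so the cartilage surface is detectable
CARTILAGE_DENSITY = 120.0


@dataclass
class PhantomSpec:
    center_yx: tuple[int, int]
    radius_vox: float
    density: float  # mg HA/ccm
    mask: np.ndarray  # 3-D bool


@dataclass
class VoxelVolume:
    """3-D grayscale volume; axis 0 (z) increases with depth from the
    articular side, voxels isotropic."""

    data: np.ndarray
    voxel_size_um: float

    def __post_init__(self) -> None:
        if self.voxel_size_um <= 0:
            raise ValueError("voxel_size_um must be positive")
        if self.data.size == 0:
            raise ValueError("volume is empty")

    @property
    def voxel_size_mm(self) -> float:
        return self.voxel_size_um / 1000.0


@dataclass
class VolumeTruth:
    bvtv: float  # realized, by counting over the specimen region
    mean_tissue_bmd: float  # mg HA/ccm, mean of assigned density over bone
    damage_fraction: float  # damaged / bone voxels within the damage zone
    bone_mask: np.ndarray
    damage_mask: np.ndarray
    specimen_footprint: np.ndarray  # 2-D bool (y, x)
    interface_z: int  # first bone slice index
    cartilage_surface_z: int
    phantoms: list[PhantomSpec] = field(default_factory=list)
    damage_zone: np.ndarray | None = None  # 3-D bool, top-1mm bone band
    lower_threshold_hint: float = 0.0  # midpoint background/tissue grayscale


def _cylinder_mask(shape_yx: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    yy, xx = np.mgrid[0:shape_yx[0], 0:shape_yx[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def generate_volume(
    shape: tuple[int, int, int] = (160, 128, 128),
    voxel_size: float = 50.0,
    target_bvtv: float = 0.85,
    tissue_bmd: float = 900.0,
    bmd_depth_gradient: float = 10.0,
    damage_fraction: float = 0.03,
    phantom_densities: tuple[float, float] = (250.0, 750.0),
    seed: int = 0,
    bvtv_depth_gradient: float = 0.0,
    cartilage_thickness_mm: float = 0.5,
    struct_sigma_vox: float = 2.5,
    noise_sd: float = 4.0,
    specimen_radius_fraction: float = 0.42,
    phantom_radius_fraction: float = 0.08,
) -> tuple[VoxelVolume, VolumeTruth]:
    """Generate a calibrated-phantom trabecular volume with known truth.

    Parameters of note: ``voxel_size`` in µm; ``target_bvtv`` the
    specimen-average bone volume fraction (realized within 0.01 by per-slice
    quantile thresholding of the structure field); ``bmd_depth_gradient`` in
    mg HA/ccm per mm of depth (positive = denser deep, as in subchondral
    bone); ``bvtv_depth_gradient`` per mm (negative = more porous deep);
    ``damage_fraction`` the fraction of bone voxels in the top 1 mm of bone,
    sampled on pore surfaces, that are rendered as stain label.
    """
    if not 0 < target_bvtv <= 1:
        raise ValueError("target_bvtv must be in (0, 1]")
    if phantom_densities[0] == phantom_densities[1]:
        raise ValueError("phantom densities must be distinct")
    if not 0 <= damage_fraction < 1:
        raise ValueError("damage_fraction must be in [0, 1)")
    nz, ny, nx = shape
    rng = np.random.default_rng(seed)
    vox_mm = voxel_size / 1000.0

    center = ((ny - 1) / 2.0, (nx - 1) / 2.0)
    spec_radius = specimen_radius_fraction * min(ny, nx)
    footprint = _cylinder_mask((ny, nx), center, spec_radius)

    cart_vox = int(round(cartilage_thickness_mm / vox_mm))
    surface_z = max(1, nz // 40)  # saline gap above the cartilage
    interface_z = surface_z + cart_vox
    if interface_z >= nz - 4:
        raise ValueError("volume too shallow for the cartilage cap")

    # --- trabecular structure from a smoothed Gaussian random field ---
    field3 = gaussian_filter(
        rng.standard_normal(shape).astype(np.float32), struct_sigma_vox
    )
    bone = np.zeros(shape, dtype=bool)
    depth_mm = (np.arange(nz) - interface_z) * vox_mm
    mid_depth = 0.5 * (nz - 1 - interface_z) * vox_mm
    fp_idx = np.where(footprint)
    for z in range(interface_z, nz):
        local = target_bvtv + bvtv_depth_gradient * (depth_mm[z] - mid_depth)
        local = min(max(local, 0.02), 1.0)
        if local >= 1.0:
            bone[z][footprint] = True
            continue
        vals = field3[z][footprint]
        thr = np.quantile(vals, 1.0 - local)
        bone[z][fp_idx] = vals >= thr

    bone_count = int(bone.sum())
    total_in_spec = int(footprint.sum()) * (nz - interface_z)
    realized_bvtv = bone_count / total_in_spec

    # --- density and grayscale ---
    density = np.zeros(shape, dtype=np.float32)
    dz = np.clip(depth_mm, 0, None)[:, None, None].astype(np.float32)
    density += np.where(bone, tissue_bmd + bmd_depth_gradient * (dz - mid_depth), 0.0)
    mean_tissue_bmd = float(density[bone].mean()) if bone_count else 0.0
    # cartilage cap: faint soft-tissue density inside the footprint
    cart = np.zeros(shape, dtype=bool)
    cart[surface_z:interface_z] = footprint
    cart &= ~bone
    density[cart] = CARTILAGE_DENSITY

    # --- calibration phantoms in the corners, outside the specimen ---
    phantoms: list[PhantomSpec] = []
    ph_radius = phantom_radius_fraction * min(ny, nx)
    corners = [(ph_radius + 2, ph_radius + 2), (ny - ph_radius - 3, nx - ph_radius - 3)]
    for (cy, cx), dens in zip(corners, phantom_densities):
        fp = _cylinder_mask((ny, nx), (cy, cx), ph_radius)
        if np.any(fp & footprint):
            raise ValueError("phantom region overlaps the specimen footprint")
        m3 = np.zeros(shape, dtype=bool)
        m3[:] = fp
        density[m3] = dens
        phantoms.append(PhantomSpec((int(cy), int(cx)), ph_radius, dens, m3))

    # --- damage labels on pore surfaces in the top 1 mm of bone ---
    zone = np.zeros(shape, dtype=bool)
    z_hi = min(nz, interface_z + int(round(1.0 / vox_mm)))
    zone[interface_z:z_hi] = True
    zone &= bone
    damage = np.zeros(shape, dtype=bool)
    realized_damage = 0.0
    zone_count = int(zone.sum())
    if damage_fraction > 0 and zone_count:
        n_want = int(round(damage_fraction * zone_count))
        surface = bone & ~binary_erosion(bone)
        cand = np.flatnonzero(surface & zone)
        if cand.size < n_want:  # widen to a two-voxel surface shell
            shell2 = bone & ~binary_erosion(bone, iterations=2)
            cand = np.flatnonzero(shell2 & zone)
        n_take = min(n_want, cand.size)
        chosen = rng.choice(cand, size=n_take, replace=False)
        damage.flat[chosen] = True
        realized_damage = n_take / zone_count

    gs = GS_PER_DENSITY * density
    gs[damage] = LABEL_GS
    gs += rng.normal(0.0, noise_sd, size=shape).astype(np.float32)
    np.clip(gs, 0.0, None, out=gs)

    volume = VoxelVolume(data=gs.astype(np.float32), voxel_size_um=voxel_size)
    truth = VolumeTruth(
        bvtv=realized_bvtv,
        mean_tissue_bmd=mean_tissue_bmd,
        damage_fraction=realized_damage,
        bone_mask=bone,
        damage_mask=damage,
        specimen_footprint=footprint,
        interface_z=interface_z,
        cartilage_surface_z=surface_z,
        phantoms=phantoms,
        damage_zone=zone,
        lower_threshold_hint=0.5 * GS_PER_DENSITY * tissue_bmd,
    )
    return volume, truth
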
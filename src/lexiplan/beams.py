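"""Toy pencil-beam dose engine for equi-angular coplanar beams.

The optimizer only needs a linear, nonnegative fluence-to-dose map. This
module provides one with documented toy physics: exponential depth
attenuation (mu, per cm) from the body entry point and a Gaussian lateral
penumbra (sigma, mm), no explicit scatter and no divergence; the default mu
is an effective broad-beam value for 10 MV (narrow-beam attenuation would
overstate depth dose fall-off in the absence of modeled scatter buildup). Each beam carries a
single 1-D row of beamlets (coplanar slab geometry) spanning the PTV's
lateral projection plus a margin; fluence does not vary along z.

Entry (i, j) of the influence matrix is::

    dose_scale * exp(-mu * depth_ij) * exp(-lat_ij^2 / (2 sigma^2))

with depth_ij the path length (mm) from the body entry to voxel i along
beamlet j's axis direction and lat_ij the in-plane perpendicular distance
from voxel i to the beamlet's central axis; entries beyond ``cutoff_sigmas``
lateral distances are dropped for sparsity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

__all__ = [
    "BeamConfig",
    "DoseInfluence",
    "DoseDistribution",
    "beam_angles",
    "compute_dose_influence",
    "dose_from_fluence",
    "save_influence",
    "load_influence",
]


@dataclass(frozen=True)
class BeamConfig:
    """Equi-angular coplanar beam set and toy dose-model parameters.

    mu approximates 10 MV attenuation (0.045 / cm); sigma is the lateral
    Gaussian penumbra in mm; dose_scale is Gy per unit fluence at zero depth.
    """

    n_beams: int = 20
    beamlet_width: float = 5.0       # mm
    mu: float = 0.035                # per cm (effective broad-beam, 10 MV)
    sigma: float = 3.0               # mm
    dose_scale: float = 1.0          # Gy per unit fluence at depth 0
    margin_mm: float = 10.0          # beamlet row margin beyond PTV projection
    cutoff_sigmas: float = 3.0
    z_margin_mm: float = 5.0         # jaw aperture margin beyond PTV z-extent
    z_sigma: float = 8.0             # jaw penumbra (mm); fluence is constant in z

    def __post_init__(self):
        if self.n_beams < 1:
            raise ValueError(f"n_beams must be >= 1, got {self.n_beams}")
        for name in ("beamlet_width", "mu", "sigma", "dose_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class Beamlet:
    beam: int
    angle_deg: float
    offset_mm: float    # lateral position of the central axis, relative to iso


@dataclass
class DoseInfluence:
    """Sparse nonnegative map (n_body_voxels x n_beamlets), Gy per unit fluence."""

    matrix: sparse.csc_matrix
    beamlets: list[Beamlet]
    voxel_rows: np.ndarray           # flat grid index per matrix row
    grid_shape: tuple[int, int, int]
    config: BeamConfig | None = None

    @property
    def n_beamlets(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_voxels(self) -> int:
        return self.matrix.shape[0]

    def rows_for_mask(self, mask: np.ndarray) -> np.ndarray:
        """Matrix row indices of the voxels in ``mask`` (body voxels only)."""
        flat = np.flatnonzero(np.asarray(mask, dtype=bool).ravel())
        lookup = -np.ones(int(np.prod(self.grid_shape)), dtype=np.int64)
        lookup[self.voxel_rows] = np.arange(len(self.voxel_rows))
        rows = lookup[flat]
        return rows[rows >= 0]


@dataclass
class DoseDistribution:
    """Per-voxel dose in Gy on the phantom grid; zero outside the body."""

    dose: np.ndarray

    def __post_init__(self):
        if np.any(self.dose < 0):
            raise ValueError("dose values must be >= 0")

    def values_in(self, mask: np.ndarray) -> np.ndarray:
        return self.dose[np.asarray(mask, dtype=bool)]


def beam_angles(n_beams: int) -> np.ndarray:
    """n equally spaced gantry angles in [0, 360) degrees, starting at 0."""
    if n_beams < 1:
        raise ValueError(f"n_beams must be >= 1, got {n_beams}")
    return np.arange(n_beams) * (360.0 / n_beams)


def compute_dose_influence(phantom, config: BeamConfig | None = None) -> DoseInfluence:
    """Build the sparse dose-influence matrix for a phantom.

    The isocenter is the PTV centroid. For gantry angle theta the source sits
    at direction (sin theta, cos theta) in the x-y plane (0 deg = anterior)
    and rays travel toward -that direction; depth is measured from the first
    body voxel along each (lateral, z) ray. Every beam is collimated in z to
    the PTV's z-extent plus ``z_margin_mm``, with a Gaussian jaw penumbra of
    ``z_sigma`` (the fluence itself does not vary along z).
    """
    config = config or BeamConfig()
    grid = phantom.grid
    body = phantom.mask("body")
    ptv = phantom.mask("ptv")
    if not body.any():
        raise ValueError("phantom body mask is empty")
    if not ptv.any():
        raise ValueError("phantom PTV mask is empty")

    vox = np.asarray(grid.voxel_size)
    body_flat = np.flatnonzero(body.ravel())
    ii, jj, kk = np.unravel_index(body_flat, grid.shape)
    xyz = np.stack([ii, jj, kk], axis=1) * vox + np.asarray(grid.origin)

    ptv_idx = np.argwhere(ptv) * vox + np.asarray(grid.origin)
    iso = ptv_idx.mean(axis=0)
    iso[2] = 0.0 if abs(iso[2]) < 1e-9 else iso[2]

    rel = xyz - iso
    zbin = np.round((xyz[:, 2] - grid.origin[2]) / vox[2]).astype(np.int64)

    # jaw collimation in z: flat inside the aperture, Gaussian penumbra outside
    z_lo = ptv_idx[:, 2].min() - config.z_margin_mm
    z_hi = ptv_idx[:, 2].max() + config.z_margin_mm
    z_out = np.maximum(0.0, np.maximum(z_lo - xyz[:, 2], xyz[:, 2] - z_hi))
    z_profile = np.exp(-(z_out ** 2) / (2.0 * config.z_sigma ** 2))
    z_profile[z_out > config.cutoff_sigmas * config.z_sigma] = 0.0

    angles = beam_angles(config.n_beams)
    sigma = config.sigma
    cutoff = config.cutoff_sigmas * sigma
    mu_mm = config.mu / 10.0          # per cm -> per mm
    vbin_size = float(min(vox[0], vox[1]))

    cols_data, cols_rows, beamlets = [], [], []
    nz = int(grid.shape[2])

    for b, ang in enumerate(angles):
        th = np.deg2rad(ang)
        # beam travels along -s where s points to the source
        s = np.array([np.sin(th), np.cos(th)])
        p = np.array([np.cos(th), -np.sin(th)])     # lateral axis
        u = -(rel[:, 0] * s[0] + rel[:, 1] * s[1])  # along-beam coordinate
        v = rel[:, 0] * p[0] + rel[:, 1] * p[1]     # lateral coordinate

        # entry depth per (lateral, z) ray, on bins of the finest in-plane
        # pitch; floor keeps bin edges between ray columns on aligned grids
        vb = np.floor(v / vbin_size).astype(np.int64)
        vb -= vb.min()
        ray = vb * nz + zbin
        entry = np.full(ray.max() + 1, np.inf)
        np.minimum.at(entry, ray, u)
        depth = u - entry[ray]

        # beamlet row spans PTV projection plus margin, centered on it
        vp = (ptv_idx[:, 0] - iso[0]) * p[0] + (ptv_idx[:, 1] - iso[1]) * p[1]
        lo, hi = vp.min() - config.margin_mm, vp.max() + config.margin_mm
        n_blt = int(np.ceil((hi - lo) / config.beamlet_width))
        if n_blt < 1:
            raise ValueError("beamlet coverage insufficient for the PTV projection")
        mid = 0.5 * (lo + hi)
        offsets = mid + (np.arange(n_blt) - (n_blt - 1) / 2.0) * config.beamlet_width

        atten = config.dose_scale * np.exp(-mu_mm * depth) * z_profile
        for off in offsets:
            lat = np.abs(v - off)
            sel = lat <= cutoff
            w = atten[sel] * np.exp(-(lat[sel] ** 2) / (2.0 * sigma ** 2))
            keep = w > 0
            cols_rows.append(np.flatnonzero(sel)[keep])
            cols_data.append(w[keep])
            beamlets.append(Beamlet(beam=b, angle_deg=float(ang), offset_mm=float(off)))

    indptr = np.zeros(len(cols_data) + 1, dtype=np.int64)
    indptr[1:] = np.cumsum([len(r) for r in cols_rows])
    matrix = sparse.csc_matrix(
        (np.concatenate(cols_data) if cols_data else np.empty(0),
         np.concatenate(cols_rows) if cols_rows else np.empty(0, dtype=np.int64),
         indptr),
        shape=(len(body_flat), len(cols_data)),
    )
    return DoseInfluence(matrix=matrix, beamlets=beamlets, voxel_rows=body_flat,
                         grid_shape=grid.shape, config=config)


def dose_from_fluence(influence: DoseInfluence, fluence: np.ndarray) -> DoseDistribution:
    """Embed ``matrix @ fluence`` on the full grid (linear, nonnegative)."""
    fluence = np.asarray(fluence, dtype=float).ravel()
    if fluence.shape[0] != influence.n_beamlets:
        raise ValueError(
            f"fluence length {fluence.shape[0]} != n_beamlets {influence.n_beamlets}"
        )
    if np.any(fluence < 0):
        raise ValueError("fluence weights must be >= 0")
    d = influence.matrix @ fluence
    full = np.zeros(int(np.prod(influence.grid_shape)))
    full[influence.voxel_rows] = d
    return DoseDistribution(dose=full.reshape(influence.grid_shape))


# ---------------------------------------------------------------------------
# persistence: sparse container plus a JSON header
# ---------------------------------------------------------------------------

def save_influence(influence: DoseInfluence, out_dir) -> None:
    """Write the sparse matrix (npz), the voxel-row map and a JSON header
    with dimensions, beamlet geometry and model parameters."""
    import json
    from dataclasses import asdict
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sparse.save_npz(out / "influence.npz", influence.matrix.tocsc())
    np.save(out / "voxel_rows.npy", influence.voxel_rows)
    header = {
        "grid_shape": list(influence.grid_shape),
        "n_beamlets": influence.n_beamlets,
        "beamlets": [
            {"beam": b.beam, "angle_deg": b.angle_deg, "offset_mm": b.offset_mm}
            for b in influence.beamlets
        ],
        "config": asdict(influence.config) if influence.config else None,
    }
    (out / "influence.json").write_text(json.dumps(header, indent=2))


def load_influence(in_dir) -> DoseInfluence:
    import json
    from pathlib import Path

    src = Path(in_dir)
    header = json.loads((src / "influence.json").read_text())
    matrix = sparse.load_npz(src / "influence.npz").tocsc()
    voxel_rows = np.load(src / "voxel_rows.npy")
    beamlets = [Beamlet(beam=b["beam"], angle_deg=b["angle_deg"],
                        offset_mm=b["offset_mm"]) for b in header["beamlets"]]
    config = BeamConfig(**header["config"]) if header.get("config") else None
    return DoseInfluence(matrix=matrix, beamlets=beamlets,
                         voxel_rows=voxel_rows,
                         grid_shape=tuple(header["grid_shape"]), config=config)
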
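"""Synthetic pelvic phantoms with planning structures.

Generates voxelized phantoms emulating the anatomy of locally advanced
cervical cancer radiotherapy: an elliptical body outline, a concave
("horseshoe") PTV wrapping the bladder anteriorly, small bowel, rectum and
sigmoid (optionally colon), plus the derived planning structures referenced
by the wish-list — dose fall-off shells at fixed distances from the PTV, a
skin ring inside the body contour, and the remaining "unspecified tissue".

All masks are boolean arrays on a regular grid; distances between voxel
centers are Euclidean (exact distance transform, anisotropic voxels
supported).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.spatial import Delaunay

__all__ = [
    "GridSpec",
    "PhantomParams",
    "Phantom",
    "GenerationError",
    "generate_phantom",
    "expand_mask",
    "shell_at",
    "skin_ring",
    "hull_fill_fraction",
    "save_phantom",
    "load_phantom",
]

#: structure names the wish-list may reference but a phantom may legitimately lack
OPTIONAL_STRUCTURES = frozenset({"colon"})


class GenerationError(RuntimeError):
    """A structure could not be realized on the requested grid."""


@dataclass(frozen=True)
class GridSpec:
    """Regular voxel grid: ``shape`` voxels per axis, ``voxel_size`` mm per axis.

    The origin is the world coordinate (mm) of the center of voxel (0,0,0).
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise ValueError(f"grid shape must be 3 positive integers, got {self.shape}")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel sizes must be > 0, got {self.voxel_size}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates (mm) of voxel centers, as three broadcastable axes."""
        axes = [
            self.origin[k] + self.voxel_size[k] * np.arange(self.shape[k])
            for k in range(3)
        ]
        return np.meshgrid(*axes, indexing="ij", sparse=True)

    def affine(self) -> np.ndarray:
        """4x4 voxel-to-world affine (for NIfTI I/O)."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.voxel_size)
        aff[:3, 3] = self.origin
        return aff


def _default_grid() -> GridSpec:
    # 5 mm isotropic, 48 x 48 x 21 voxels (240 x 240 x 105 mm), centered on iso
    shape = (48, 48, 21)
    vox = (5.0, 5.0, 5.0)
    origin = tuple(-(s - 1) * v / 2.0 for s, v in zip(shape, vox))
    return GridSpec(shape, vox, origin)


@dataclass(frozen=True)
class PhantomParams:
    """Generator parameters (mm unless noted).

    ``concavity`` in [0, 1] controls how deeply the bladder carves into the
    target, emulating the difference between full-bladder (shallow wrap) and
    empty-bladder (deep horseshoe) target volumes.
    """

    grid: GridSpec = field(default_factory=_default_grid)
    concavity: float = 0.6
    margin_mm: float = 10.0          # ITV -> PTV isotropic expansion
    body_semiaxes: tuple[float, float, float] = (108.0, 92.0, 70.0)
    itv_radius: float = 28.0         # in-plane radius of the target column
    itv_half_height: float = 24.0    # half z-extent of the target column
    bladder_radius: float = 18.0
    small_bowel_radius: float = 13.0
    rectum_radius: float = 11.0
    sigmoid_radius: float = 8.0
    colon_radius: float = 9.0
    with_colon: bool = False
    jitter_mm: float = 2.0           # seed-controlled random displacement scale
    shell_distances_mm: tuple[float, ...] = (3.0, 15.0, 25.0, 40.0)
    shell_thickness_mm: float | None = None   # default: 2 voxel widths
    skin_width_mm: float = 20.0

    def validate(self) -> None:
        if not (0.0 <= self.concavity <= 1.0):
            raise ValueError(f"concavity must be in [0, 1], got {self.concavity}")
        if self.margin_mm < 0:
            raise ValueError(f"margin_mm must be >= 0, got {self.margin_mm}")
        if self.grid.n_voxels < 32 ** 3:
            raise ValueError(
                f"grid too coarse: {self.grid.n_voxels} voxels < 32^3 equivalents"
            )
        if self.itv_half_height <= 0:
            raise ValueError(f"itv_half_height must be > 0, got {self.itv_half_height}")
        for name in ("itv_radius", "bladder_radius", "small_bowel_radius",
                     "rectum_radius", "sigmoid_radius", "colon_radius"):
            r = getattr(self, name)
            if r <= 0:
                raise ValueError(f"{name} must be > 0, got {r}")
            if r >= min(self.body_semiaxes):
                raise ValueError(f"{name}={r} does not fit inside body {self.body_semiaxes}")
        if self.jitter_mm < 0:
            raise ValueError(f"jitter_mm must be >= 0, got {self.jitter_mm}")
        if any(d <= 0 for d in self.shell_distances_mm):
            raise ValueError("shell distances must be > 0")
        if self.skin_width_mm <= 0:
            raise ValueError("skin_width_mm must be > 0")


@dataclass
class Phantom:
    """Voxel grid plus named binary structure masks."""

    grid: GridSpec
    structures: dict[str, np.ndarray]
    seed: int = 0
    params: PhantomParams | None = None

    def __post_init__(self):
        for name, mask in self.structures.items():
            if mask.shape != self.grid.shape:
                raise ValueError(
                    f"mask {name!r} has shape {mask.shape}, grid is {self.grid.shape}"
                )

    def mask(self, name: str) -> np.ndarray:
        try:
            return self.structures[name]
        except KeyError:
            raise KeyError(f"phantom has no structure named {name!r}") from None

    @property
    def names(self) -> list[str]:
        return list(self.structures)


# ---------------------------------------------------------------------------
# mask morphology (exact Euclidean, voxel-center semantics)
# ---------------------------------------------------------------------------

def _distance_to_mask(mask: np.ndarray, voxel_size) -> np.ndarray:
    """Euclidean distance (mm) from each voxel center to the nearest mask voxel
    center; 0 inside the mask."""
    if not mask.any():
        return np.full(mask.shape, np.inf)
    return ndimage.distance_transform_edt(~mask, sampling=voxel_size)


def expand_mask(mask: np.ndarray, margin_mm: float, voxel_size=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Isotropic expansion: all voxels whose center lies within ``margin_mm``
    (Euclidean) of any input voxel center. Superset of the input."""
    if margin_mm < 0:
        raise ValueError(f"margin_mm must be >= 0, got {margin_mm}")
    mask = np.asarray(mask, dtype=bool)
    if margin_mm == 0 or not mask.any():
        return mask.copy()
    return _distance_to_mask(mask, voxel_size) <= margin_mm


def shell_at(ptv: np.ndarray, distance_mm: float, thickness_mm: float,
             voxel_size=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Thin ring centered at ``distance_mm`` from the PTV surface.

    Voxels whose center-to-PTV distance d satisfies
    ``distance - thickness/2 < d <= distance + thickness/2``; disjoint from
    the PTV by construction and clipped to the grid.
    """
    if distance_mm <= 0:
        raise ValueError(f"distance_mm must be > 0, got {distance_mm}")
    if thickness_mm <= 0:
        raise ValueError(f"thickness_mm must be > 0, got {thickness_mm}")
    ptv = np.asarray(ptv, dtype=bool)
    if not ptv.any():
        raise ValueError("shell_at requires a nonempty PTV")
    d = _distance_to_mask(ptv, voxel_size)
    lo = distance_mm - thickness_mm / 2.0
    hi = distance_mm + thickness_mm / 2.0
    return (d > lo) & (d <= hi) & (d > 0)


def skin_ring(body: np.ndarray, width_mm: float, voxel_size=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Body voxels within ``width_mm`` (Euclidean, center-to-center) of the
    body's outer boundary (the complement). Subset of body."""
    if width_mm <= 0:
        raise ValueError(f"width_mm must be > 0, got {width_mm}")
    body = np.asarray(body, dtype=bool)
    if not body.any():
        raise ValueError("skin_ring requires a nonempty body")
    # distance from each body voxel center to the nearest non-body voxel center
    d_out = ndimage.distance_transform_edt(body, sampling=voxel_size)
    return body & (d_out <= width_mm)


def hull_fill_fraction(mask: np.ndarray, grid: GridSpec) -> float:
    """Mask volume divided by the volume of its convex hull, both counted in
    voxels on the same grid. 1.0 for convex shapes; decreases with concavity."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("hull_fill_fraction requires a nonempty mask")
    idx = np.argwhere(mask).astype(float)
    pts = idx * np.asarray(grid.voxel_size)
    try:
        tri = Delaunay(pts)
    except Exception as exc:  # degenerate (coplanar) point sets
        raise ValueError(f"convex hull undefined for this mask: {exc}") from exc
    all_idx = np.argwhere(np.ones(grid.shape, dtype=bool)).astype(float)
    all_pts = all_idx * np.asarray(grid.voxel_size)
    inside = tri.find_simplex(all_pts) >= 0
    return float(mask.sum()) / float(inside.sum())


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------

def _ball(X, Y, Z, center, radius) -> np.ndarray:
    return ((X - center[0]) ** 2 + (Y - center[1]) ** 2 + (Z - center[2]) ** 2) <= radius ** 2


def _tube(X, Y, Z, points, radius) -> np.ndarray:
    """Union of balls along a polyline sampled densely (simple organ tubes)."""
    mask = np.zeros(np.broadcast(X, Y, Z).shape, dtype=bool)
    pts = np.asarray(points, dtype=float)
    for a, b in zip(pts[:-1], pts[1:]):
        n = max(2, int(np.ceil(np.linalg.norm(b - a) / (radius / 2.0))) + 1)
        for t in np.linspace(0.0, 1.0, n):
            mask |= _ball(X, Y, Z, a + t * (b - a), radius)
    return mask


def generate_phantom(seed: int, params: PhantomParams | None = None) -> Phantom:
    """Generate a reproducible synthetic pelvic phantom.

    Axes: +x patient-left, +y anterior, +z superior, world origin at the
    isocenter. The target (ITV) is a ball posterior to the bladder; the
    bladder carves into it by a depth controlled by ``concavity``, and the
    ITV->PTV margin expansion then produces the concave horseshoe PTV.
    Identical (seed, params) yield bit-identical masks.
    """
    params = params or PhantomParams()
    params.validate()
    grid = params.grid
    rng = np.random.default_rng(seed)
    jit = lambda scale=1.0: rng.uniform(-params.jitter_mm, params.jitter_mm) * scale

    X, Y, Z = grid.coords()
    vox = grid.voxel_size

    ax, ay, az = params.body_semiaxes
    body = (X / ax) ** 2 + (Y / ay) ** 2 + (Z / az) ** 2 <= 1.0

    # target: elongated cervix-uterus column carved by the (dilated) bladder
    tc = np.array([jit(0.5), -5.0 + jit(0.5), jit(0.5)])
    R = params.itv_radius + jit(0.3)
    H = params.itv_half_height + jit(0.3)
    rb = params.bladder_radius + jit(0.3)
    # bladder penetrates the target column by depth o(concavity)
    overlap = 4.0 + 0.8 * params.concavity * R
    bc = np.array([tc[0] + jit(0.3), tc[1] + R + rb - overlap, tc[2] + jit(0.3)])
    bladder = _ball(X, Y, Z, bc, rb)
    column = (((X - tc[0]) ** 2 + (Y - tc[1]) ** 2) <= R ** 2) & (np.abs(Z - tc[2]) <= H)
    itv = column & ~_ball(X, Y, Z, bc, rb + 4.0)
    ptv = expand_mask(itv, params.margin_mm, vox) & body

    # small bowel: bag of loops superior-anterior of the target
    sb = np.zeros(grid.shape, dtype=bool)
    z_hi = tc[2] + H + params.margin_mm
    for k in range(6):
        c = np.array([
            -45.0 + 18.0 * k + jit(),
            25.0 + 10.0 * np.sin(k * 1.3) + jit(),
            z_hi - 4.0 + 6.0 * np.cos(k * 0.9) + jit(),
        ])
        sb |= _ball(X, Y, Z, c, params.small_bowel_radius + jit(0.2))
    sb &= body & ~ptv & ~bladder

    # rectum: posterior tube along z
    y_r = tc[1] - R - params.margin_mm - params.rectum_radius + 3.0
    rect_pts = [
        (jit(0.5), y_r + jit(0.3), grid.origin[2]),
        (jit(0.5), y_r + jit(0.3), tc[2] + 12.0),
    ]
    rectum = _tube(X, Y, Z, rect_pts, params.rectum_radius) & body & ~ptv & ~bladder

    # sigmoid: curved tube from the rectum top toward the small-bowel region
    sig_pts = [
        (0.0 + jit(0.5), y_r + jit(0.5), tc[2] + 10.0),
        (-12.0 + jit(0.5), y_r + 14.0 + jit(0.5), z_hi + jit(0.5)),
        (-20.0 + jit(0.5), 5.0 + jit(0.5), z_hi + 8.0 + jit(0.5)),
    ]
    sigmoid = _tube(X, Y, Z, sig_pts, params.sigmoid_radius) & body & ~ptv & ~bladder & ~rectum & ~sb

    structures: dict[str, np.ndarray] = {
        "body": body,
        "ptv": ptv,
        "bladder": bladder & body,
        "small_bowel": sb,
        "rectum": rectum,
        "sigmoid": sigmoid,
    }

    if params.with_colon:
        col_pts = [
            (-60.0 + jit(0.5), 30.0 + jit(0.5), z_hi + 6.0),
            (0.0 + jit(0.5), 55.0 + jit(0.5), z_hi + 10.0),
            (60.0 + jit(0.5), 30.0 + jit(0.5), z_hi + 6.0),
        ]
        colon = _tube(X, Y, Z, col_pts, params.colon_radius) & body & ~ptv & ~bladder & ~sb & ~sigmoid
        structures["colon"] = colon

    thickness = params.shell_thickness_mm or 2.0 * min(vox)
    for dist in params.shell_distances_mm:
        name = f"shell_{dist:g}mm"
        structures[name] = shell_at(ptv, dist, thickness, vox) & body

    structures["skin_ring"] = skin_ring(body, params.skin_width_mm, vox)

    organ_names = ["bladder", "small_bowel", "rectum", "sigmoid"] + (
        ["colon"] if params.with_colon else [])
    oars = np.zeros(grid.shape, dtype=bool)
    for n in organ_names:
        oars |= structures[n]
    structures["unspecified_tissue"] = body & ~ptv & ~oars

    required = ["body", "ptv", "bladder", "small_bowel", "rectum", "sigmoid",
                "skin_ring", "unspecified_tissue"] + [
                    f"shell_{d:g}mm" for d in params.shell_distances_mm]
    for name in required:
        if not structures[name].any():
            raise GenerationError(
                f"structure {name!r} is empty at grid {grid.shape}; "
                "increase resolution or organ size"
            )

    return Phantom(grid=grid, structures=structures, seed=int(seed), params=params)


# ---------------------------------------------------------------------------
# I/O: one NIfTI per structure plus a JSON sidecar
# ---------------------------------------------------------------------------

def save_phantom(phantom: Phantom, out_dir: str | Path) -> Path:
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aff = phantom.grid.affine()
    for name, mask in phantom.structures.items():
        img = nib.Nifti1Image(mask.astype(np.uint8), aff)
        nib.save(img, out / f"{name}.nii.gz")
    sidecar = {
        "grid": {
            "shape": list(phantom.grid.shape),
            "voxel_size": list(phantom.grid.voxel_size),
            "origin": list(phantom.grid.origin),
        },
        "structures": list(phantom.structures),
        "seed": phantom.seed,
        "params": _params_to_json(phantom.params) if phantom.params else None,
    }
    (out / "phantom.json").write_text(json.dumps(sidecar, indent=2))
    return out


def _params_to_json(params: PhantomParams) -> dict:
    d = asdict(params)
    d["grid"] = {
        "shape": list(params.grid.shape),
        "voxel_size": list(params.grid.voxel_size),
        "origin": list(params.grid.origin),
    }
    return d


def _params_from_json(d: dict) -> PhantomParams:
    d = dict(d)
    g = d.pop("grid")
    grid = GridSpec(tuple(g["shape"]), tuple(g["voxel_size"]), tuple(g["origin"]))
    for key in ("body_semiaxes", "shell_distances_mm"):
        if key in d and d[key] is not None:
            d[key] = tuple(d[key])
    return PhantomParams(grid=grid, **d)


def load_phantom(in_dir: str | Path) -> Phantom:
    import nibabel as nib

    src = Path(in_dir)
    sidecar = json.loads((src / "phantom.json").read_text())
    g = sidecar["grid"]
    grid = GridSpec(tuple(g["shape"]), tuple(g["voxel_size"]), tuple(g["origin"]))
    structures = {}
    for name in sidecar["structures"]:
        img = nib.load(src / f"{name}.nii.gz")
        structures[name] = np.asarray(img.dataobj).astype(bool)
    params = _params_from_json(sidecar["params"]) if sidecar.get("params") else None
    return Phantom(grid=grid, structures=structures, seed=sidecar.get("seed", 0),
                   params=params)
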
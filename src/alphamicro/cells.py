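"""Voxelized cell geometries: label volumes, threshold segmentation,
exact ray-voxel path lengths (tau1/tau2/tau3) and synthetic cells.

Label convention follows the segmentation files this package consumes:
8-bit values 0 (background / medium), 182 (cytoplasm), 201 (nucleus).

Coordinates: voxel indices are 0-based; the world position of the corner of
voxel (0,0,0) is ``origin`` (um); a voxel's center sits at
origin + (index + 0.5) * voxel_size.  Arrays are stored [z, y, x] (page,
row, column), voxel sizes are given as (x, y, z) in nm.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from enum import IntEnum
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .physics import MYLAR, MaterialModel

__all__ = [
    "Label",
    "LabelVolume",
    "PathLengths",
    "segment",
    "nucleus_volume",
    "expected_voxel_count",
    "shell_volume_uncertainty",
    "ray_segments",
    "trace_path",
    "generate_synthetic_cell",
    "write_labels",
    "read_labels",
]


class Label(IntEnum):
    BACKGROUND = 0
    CYTOPLASM = 182
    NUCLEUS = 201


_LEGAL = frozenset(int(v) for v in Label)


@dataclass(frozen=True)
class LabelVolume:
    labels: np.ndarray  # uint8, shape (nz, ny, nx)
    voxel_size: tuple  # (x, y, z) nm
    origin: np.ndarray = None  # (x, y, z) um, corner of voxel (0,0,0)

    def __post_init__(self) -> None:
        lab = np.ascontiguousarray(self.labels, dtype=np.uint8)
        if lab.ndim != 3:
            raise ValueError("labels must be a 3-D array")
        extra = set(np.unique(lab)) - _LEGAL
        if extra:
            raise ValueError(f"illegal label values {sorted(extra)}")
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError("voxel_size must be three positive values (nm)")
        origin = np.zeros(3) if self.origin is None else np.asarray(self.origin, float)
        object.__setattr__(self, "labels", lab)
        object.__setattr__(self, "voxel_size", vs)
        object.__setattr__(self, "origin", origin)

    @property
    def voxel_um(self) -> np.ndarray:
        """Voxel edge lengths (x, y, z) in um."""
        return np.asarray(self.voxel_size) * 1e-3

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.voxel_um))

    @property
    def shape_xyz(self) -> tuple:
        nz, ny, nx = self.labels.shape
        return (nx, ny, nz)

    @property
    def size_um(self) -> np.ndarray:
        """Physical extent (x, y, z) in um."""
        return np.asarray(self.shape_xyz) * self.voxel_um

    def with_origin(self, origin) -> "LabelVolume":
        return dataclasses.replace(self, origin=np.asarray(origin, float))

    def count(self, label: Label) -> int:
        return int(np.count_nonzero(self.labels == int(label)))


@dataclass(frozen=True)
class PathLengths:
    """Per-medium path lengths of one track: mylar, cytoplasm, nucleus (um)."""

    tau1: float
    tau2: float
    tau3: float


# ------------------------------------------------------- segmentation ----

def segment(cyto_stack, nuc_stack, cyto_threshold, nuc_threshold,
            voxel_size=(96.0, 96.0, 430.0), origin=None) -> LabelVolume:
    """Threshold two co-registered intensity stacks into a label volume.

    A voxel is nucleus (201) when the nucleus stain is at or above its
    threshold — nucleus takes precedence — else cytoplasm (182) when the
    cytoplasm stain reaches its threshold, else background (0).
    """
    cyto = np.asarray(cyto_stack)
    nuc = np.asarray(nuc_stack)
    if cyto.shape != nuc.shape:
        raise ValueError(f"stack shapes differ: {cyto.shape} vs {nuc.shape}")
    labels = np.zeros(cyto.shape, dtype=np.uint8)
    labels[cyto >= cyto_threshold] = int(Label.CYTOPLASM)
    labels[nuc >= nuc_threshold] = int(Label.NUCLEUS)
    return LabelVolume(labels, voxel_size, origin)


def nucleus_volume(vol: LabelVolume) -> float:
    """Nucleus volume (um^3): voxel count x voxel volume."""
    return vol.count(Label.NUCLEUS) * vol.voxel_volume_um3


def expected_voxel_count(volume_um3: float, voxel_volume_nm3: float) -> float:
    """Voxels occupied by a structure of the given volume (1 um^3 = 1e9 nm^3)."""
    return volume_um3 * 1e9 / voxel_volume_nm3


def shell_volume_uncertainty(vol: LabelVolume) -> float:
    """Relative nucleus-volume error of a 1-voxel radius misestimate.

    The nucleus is reduced to a sphere of equal volume; its radius r is
    expressed in isotropic-equivalent voxels (edge = cube root of the voxel
    volume).  The returned fraction is ((r+1)^3 - r^3)/r^3 = 3/r + 3/r^2 +
    1/r^3, the volume of a 1-voxel-thick shell relative to the sphere.
    """
    n = vol.count(Label.NUCLEUS)
    if n == 0:
        raise ValueError("nucleus is empty")
    r = (3.0 * n / (4.0 * np.pi)) ** (1.0 / 3.0)
    return 3.0 / r + 3.0 / r**2 + 1.0 / r**3


# ---------------------------------------------------- ray traversal ------

def ray_segments(vol: LabelVolume, origin_um, direction, t_max=np.inf):
    """Exact voxel-walking traversal of a world-space ray through the grid.

    Returns ``(t0, t1, labels)``: entry/exit distances (um, measured from
    ``origin_um`` along the unit ``direction``) and the label of each voxel
    interval crossed, ordered by distance and truncated at ``t_max``.
    """
    h = vol.voxel_um  # (hx, hy, hz)
    o = np.asarray(origin_um, float) - vol.origin
    d = np.asarray(direction, float)
    n = np.asarray(vol.shape_xyz)
    box = n * h

    t_lo, t_hi = 0.0, float(t_max)
    for a in range(3):
        if abs(d[a]) < 1e-12:
            if not (0.0 <= o[a] <= box[a]):
                return (np.empty(0), np.empty(0), np.empty(0, dtype=np.uint8))
        else:
            ta = (0.0 - o[a]) / d[a]
            tb = (box[a] - o[a]) / d[a]
            t_lo = max(t_lo, min(ta, tb))
            t_hi = min(t_hi, max(ta, tb))
    if t_hi <= t_lo:
        return (np.empty(0), np.empty(0), np.empty(0, dtype=np.uint8))

    ts = [np.array([t_lo, t_hi])]
    for a in range(3):
        if abs(d[a]) < 1e-12:
            continue
        pa, pb = o[a] + t_lo * d[a], o[a] + t_hi * d[a]
        lo, hi = min(pa, pb), max(pa, pb)
        k = np.arange(np.ceil(lo / h[a]), np.floor(hi / h[a]) + 1)
        ts.append((k * h[a] - o[a]) / d[a])
    t = np.unique(np.concatenate(ts))
    t = t[(t >= t_lo - 1e-12) & (t <= t_hi + 1e-12)]
    if len(t) < 2:
        return (np.empty(0), np.empty(0), np.empty(0, dtype=np.uint8))
    mid = 0.5 * (t[:-1] + t[1:])
    pos = o[None, :] + mid[:, None] * d[None, :]
    idx = np.floor(pos / h[None, :]).astype(np.int64)
    idx = np.clip(idx, 0, n[None, :] - 1)
    lab = vol.labels[idx[:, 2], idx[:, 1], idx[:, 0]]
    return (t[:-1], t[1:], lab)


def trace_path(track, vol: LabelVolume, mylar_thickness: float = 1.4,
               mylar: MaterialModel = MYLAR) -> PathLengths:
    """Path lengths through mylar (tau1), cytoplasm (tau2) and nucleus
    (tau3) for one track, truncated at the particle's residual range.

    tau1 is the slant path through the foil, mylar_thickness/|dz|.  The
    label volume is traversed exactly; everything beyond the foil slows the
    particle like water, so the stop point lies at a water path length equal
    to the residual range after the foil.
    """
    from . import physics

    d = track.direction
    if abs(d[2]) < 1e-9:
        return PathLengths(np.inf, 0.0, 0.0)
    tau1 = mylar_thickness / abs(d[2])
    e_after = physics.residual_energy(track.energy, tau1, mylar)
    if e_after <= 0.0:
        return PathLengths(tau1, 0.0, 0.0)
    t_stop = tau1 + physics.WATER.range_water(e_after)
    t0, t1, lab = ray_segments(vol, track.entry, d, t_max=t_stop)
    seg = np.clip(t1, None, t_stop) - t0
    tau2 = float(seg[lab == int(Label.CYTOPLASM)].sum())
    tau3 = float(seg[lab == int(Label.NUCLEUS)].sum())
    return PathLengths(tau1, tau2, tau3)


# ----------------------------------------------------- synthetic cell ----

def generate_synthetic_cell(
    nucleus_radius,
    cyto_margin: float = 2.0,
    voxel_size=(96.0, 96.0, 430.0),
    seed: int | None = None,
) -> LabelVolume:
    """Ellipsoidal nucleus centred inside an ellipsoidal cytoplasm.

    ``nucleus_radius`` is a scalar (sphere) or (a, b, c) semi-axes in um;
    the cytoplasm ellipsoid adds ``cyto_margin`` um to every semi-axis.
    The seed jitters the centre by up to half a voxel so that repeated
    cells do not all share the same voxelization phase.
    """
    r_n = np.broadcast_to(np.asarray(nucleus_radius, float), (3,)).copy()
    if np.any(r_n <= 0) or cyto_margin < 0:
        raise ValueError("radii must be positive and margin non-negative")
    r_c = r_n + cyto_margin
    h = np.asarray(voxel_size, float) * 1e-3  # um, (x, y, z)
    n_xyz = np.ceil(2 * (r_c + h) / h).astype(int)
    if np.any(n_xyz > 4096):
        raise ValueError("cell does not fit a reasonable grid at this voxel size")
    rng = np.random.default_rng(seed)
    center = n_xyz * h / 2 + rng.uniform(-0.5, 0.5, size=3) * h
    nx, ny, nz = n_xyz
    x = (np.arange(nx) + 0.5) * h[0] - center[0]
    y = (np.arange(ny) + 0.5) * h[1] - center[1]
    z = (np.arange(nz) + 0.5) * h[2] - center[2]
    zz, yy, xx = np.meshgrid(z, y, x, indexing="ij")
    q_n = (xx / r_n[0]) ** 2 + (yy / r_n[1]) ** 2 + (zz / r_n[2]) ** 2
    labels = np.zeros((nz, ny, nx), dtype=np.uint8)
    if cyto_margin > 0:
        q_c = (xx / r_c[0]) ** 2 + (yy / r_c[1]) ** 2 + (zz / r_c[2]) ** 2
        labels[q_c <= 1.0] = int(Label.CYTOPLASM)
    labels[q_n <= 1.0] = int(Label.NUCLEUS)
    return LabelVolume(labels, tuple(voxel_size))


# ----------------------------------------------------------------- I/O ----

def write_labels(vol: LabelVolume, path) -> None:
    """Multi-page 8-bit TIFF plus a YAML sidecar with voxel size and origin."""
    path = Path(path)
    tifffile.imwrite(path, vol.labels)
    meta = {
        "voxel_size_nm": [float(v) for v in vol.voxel_size],
        "origin_um": [float(v) for v in vol.origin],
    }
    path.with_suffix(path.suffix + ".yaml").write_text(yaml.safe_dump(meta))


def read_labels(path) -> LabelVolume:
    path = Path(path)
    labels = tifffile.imread(path)
    sidecar = path.with_suffix(path.suffix + ".yaml")
    if sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text())
        return LabelVolume(labels, tuple(meta["voxel_size_nm"]), meta.get("origin_um"))
    return LabelVolume(labels, (96.0, 96.0, 430.0))
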
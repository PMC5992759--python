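"""Alpha-track data model, TSV I/O, rim filtering, field dose and a
synthetic collimated-source generator.

A track is recorded at the top of the mylar foil: entry position (um),
a unit direction vector with positive z pointing down into the cell layer,
and the kinetic energy on arrival (keV).  Storing directions as unit
vectors rather than angle pairs avoids convention drift.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import physics
from .physics import KEV_TO_J, MYLAR, WATER_DENSITY_KG_M3

__all__ = [
    "AlphaTrack",
    "TrackField",
    "EnergyLaw",
    "read_tracks",
    "write_tracks",
    "filter_edge_tracks",
    "total_dose",
    "generate_collimated_field",
]

_COLUMNS = ["x_um", "y_um", "z_um", "dx", "dy", "dz", "energy_kev"]
_END_COLUMNS = ["end_x_um", "end_y_um", "end_z_um"]


@dataclass(frozen=True)
class AlphaTrack:
    entry: np.ndarray  # (3,) um, z = 0 at mylar top
    direction: np.ndarray  # (3,) unit vector, dz > 0 into the cells
    energy: float  # keV at the mylar top
    end_point: Optional[np.ndarray] = None  # measured terminus, if any

    def __post_init__(self) -> None:
        entry = np.asarray(self.entry, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        norm = float(np.linalg.norm(d))
        if abs(norm - 1.0) > 1e-6:
            raise ValueError(f"direction norm {norm:.8f} is not 1")
        object.__setattr__(self, "entry", entry)
        object.__setattr__(self, "direction", d / norm)
        if self.energy <= 0:
            raise ValueError("track energy must be positive")
        if self.end_point is not None:
            object.__setattr__(self, "end_point", np.asarray(self.end_point, dtype=float))


@dataclass
class TrackField:
    """A collection of tracks over a lateral field of given area (um^2)."""

    tracks: Sequence[AlphaTrack]
    area: float
    d_total: Optional[float] = None  # Gy, set by total_dose()
    extent: Optional[tuple] = None  # (Lx, Ly) um if rectangular

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError("field area must be positive")
        self.tracks = list(self.tracks)

    @property
    def n_total(self) -> int:
        return len(self.tracks)

    # vectorized views, used by the dose and microdose engines
    def entries(self) -> np.ndarray:
        return np.array([t.entry for t in self.tracks], dtype=float).reshape(-1, 3)

    def directions(self) -> np.ndarray:
        return np.array([t.direction for t in self.tracks], dtype=float).reshape(-1, 3)

    def energies(self) -> np.ndarray:
        return np.array([t.energy for t in self.tracks], dtype=float)


# ---------------------------------------------------------------- I/O ----

def write_tracks(fld: TrackField, path) -> None:
    """Write the TSV dialect: header x_um y_um z_um dx dy dz energy_kev
    [end_x_um end_y_um end_z_um], with ``#`` metadata lines first."""
    has_end = all(t.end_point is not None for t in fld.tracks)
    cols = _COLUMNS + (_END_COLUMNS if has_end else [])
    rows = []
    for t in fld.tracks:
        row = [*t.entry, *t.direction, t.energy]
        if has_end:
            row += list(t.end_point)
        rows.append(row)
    df = pd.DataFrame(rows, columns=cols)
    with open(path, "w") as fh:
        fh.write(f"# area_um2={fld.area!r}\n")
        if fld.extent is not None:
            fh.write(f"# extent_um={fld.extent[0]!r},{fld.extent[1]!r}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.9g")


def read_tracks(path) -> TrackField:
    """Read a track TSV; inverse of :func:`write_tracks`."""
    import io

    path = Path(path)
    meta = {}
    lines = path.read_text().splitlines(keepends=True)
    body_start = 0
    for line in lines:
        if not line.startswith("#"):
            break
        key, _, val = line[1:].strip().partition("=")
        meta[key.strip()] = val.strip()
        body_start += 1
    df = pd.read_csv(io.StringIO("".join(lines[body_start:])), sep="\t")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    has_end = all(c in df.columns for c in _END_COLUMNS)
    tracks = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        vals = np.asarray(row, dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"{path}: non-numeric or non-finite values on line {i}")
        d = vals[3:6]
        norm = np.linalg.norm(d)
        if abs(norm - 1.0) > 1e-6:
            raise ValueError(f"{path}: non-unit direction (|d|={norm:.8f}) on line {i}")
        end = vals[7:10] if has_end else None
        tracks.append(AlphaTrack(vals[0:3], d / norm, float(vals[6]), end))
    area = float(meta.get("area_um2", "nan"))
    extent = None
    if "extent_um" in meta:
        extent = tuple(float(v) for v in meta["extent_um"].split(","))
    if not np.isfinite(area):
        if extent is not None:
            area = extent[0] * extent[1]
        else:
            raise ValueError(f"{path}: missing '# area_um2=' metadata line")
    return TrackField(tracks, area=area, extent=extent)


# ------------------------------------------------------------- filter ----

def filter_edge_tracks(fld: TrackField, stack_bounds, rim: float = 1.0) -> TrackField:
    """Drop tracks whose end point lies within ``rim`` um of any face of the
    read-out stack; such tracks likely left the field of view before
    stopping and carry unreliable energies.

    ``stack_bounds`` is ((x0, x1), (y0, y1), (z0, z1)) in um.
    """
    if rim < 0:
        raise ValueError("rim must be non-negative")
    if rim == 0:
        return replace(fld, tracks=list(fld.tracks))
    bounds = np.asarray(stack_bounds, dtype=float).reshape(3, 2)
    kept = []
    for t in fld.tracks:
        if t.end_point is None:
            raise ValueError(
                "tracks lack end points; skip the rim filter for synthetic fields"
            )
        p = t.end_point
        near = np.any(p - bounds[:, 0] < rim) or np.any(bounds[:, 1] - p < rim)
        if not near:
            kept.append(t)
    return replace(fld, tracks=kept)


# --------------------------------------------------------------- dose ----

def total_dose(
    fld: TrackField,
    layer_thickness: float = 8.0,
    mylar_thickness: float = 1.4,
    store: bool = True,
) -> float:
    """Absorbed dose (Gy) delivered by the field to a water layer of
    ``layer_thickness`` um sitting on top of a mylar foil.

    Each track crosses the foil (path 1.4/|dz|, mylar-scaled water), then
    deposits energy over its chord through the layer, truncated where the
    particle stops.  The layer mass is area x thickness x 1000 kg/m^3.
    """
    if fld.n_total == 0:
        dose = 0.0
    else:
        dz = fld.directions()[:, 2]
        energies = fld.energies()
        down = dz > 1e-9  # tracks without a downward component never reach the layer
        sec = 1.0 / np.clip(dz, 1e-9, None)
        e_layer = physics.residual_energy(energies, mylar_thickness * sec, MYLAR)
        # chord through the layer; energy_deposited truncates at the stop point
        dep = physics.energy_deposited(e_layer, layer_thickness * sec)
        dep = np.where(down & (e_layer > 0), dep, 0.0)
        mass_kg = fld.area * layer_thickness * 1e-18 * WATER_DENSITY_KG_M3
        dose = float(np.sum(dep) * KEV_TO_J / mass_kg)
    if store:
        fld.d_total = dose
    return dose


# ---------------------------------------------------------- generator ----

@dataclass(frozen=True)
class EnergyLaw:
    """Entry-energy spectrum for synthetic fields.

    kind 'normal': truncated normal (at zero) with mean/sd in keV — a
    configurable stand-in for the degraded Am-241 spectrum at the dish,
    which is measured, not published.  kind 'delta': monoenergetic.
    """

    kind: str = "normal"
    mean: float = 4500.0
    sd: float = 200.0

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "delta":
            return np.full(n, self.mean)
        if self.kind == "normal":
            e = rng.normal(self.mean, self.sd, size=n)
            while np.any(e <= 0):  # truncate at zero, keep count fixed
                bad = e <= 0
                e[bad] = rng.normal(self.mean, self.sd, size=int(bad.sum()))
            return e
        raise ValueError(f"unknown energy law kind {self.kind!r}")


def generate_collimated_field(
    n: int,
    area: float,
    max_polar: float = 45.0,
    energy_law: EnergyLaw | None = None,
    seed: int | None = None,
) -> TrackField:
    """Synthetic collimated field: entries uniform over a square of the
    given area, azimuth uniform, polar angle uniform in solid angle within
    the cone ``polar <= max_polar`` (degrees), energies from ``energy_law``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 < max_polar <= 90:
        raise ValueError("max_polar must be in (0, 90] degrees")
    energy_law = energy_law or EnergyLaw()
    rng = np.random.default_rng(seed)
    side = float(np.sqrt(area))
    xy = rng.uniform(0.0, side, size=(n, 2))
    cos_min = np.cos(np.deg2rad(max_polar))
    cos_t = rng.uniform(cos_min, 1.0, size=n)  # uniform in solid angle
    sin_t = np.sqrt(1.0 - cos_t**2)
    phi = rng.uniform(0.0, 2 * np.pi, size=n)
    dirs = np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])
    energies = energy_law.sample(n, rng)
    tracks = [
        AlphaTrack(np.array([x, y, 0.0]), d, e)
        for (x, y), d, e in zip(xy, dirs, energies)
    ]
    return TrackField(tracks, area=area, extent=(side, side))
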
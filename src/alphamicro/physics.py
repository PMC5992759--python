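"""Alpha-particle stopping power, CSDA range and energy loss along chords.

Transport is continuous slowing down only: the particle loses energy at the
local LET, with no straggling, scattering or delta-ray escape.  That is the
right level of detail for chord x LET dose estimates in micrometre targets.

The stopping medium is liquid water (the cell nucleus, cytoplasm and culture
medium are all treated as water at 1000 kg/m^3).  Mylar is modelled as scaled
water: a path length ``t`` of mylar slows the particle like
``t * water_equivalence_factor`` of water.

Energies are keV, lengths micrometres, LET keV/um throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "StoppingPowerTable",
    "MaterialModel",
    "WATER",
    "MYLAR",
    "E_CUTOFF_KEV",
    "let_water",
    "csda_range",
    "residual_energy",
    "energy_deposited",
]

#: Below this kinetic energy the particle is stopped and deposits the
#: remainder locally; residual ranges down there are far below a voxel.
E_CUTOFF_KEV = 10.0

KEV_TO_J = 1.602176634e-16
WATER_DENSITY_KG_M3 = 1000.0


def _load_default_table() -> tuple[np.ndarray, np.ndarray]:
    text = resources.files("alphamicro.data").joinpath("alpha_water_let.tsv").read_text()
    rows = [ln.split() for ln in text.splitlines() if ln and not ln.startswith("#")]
    arr = np.asarray(rows, dtype=float)
    return arr[:, 0], arr[:, 1]


@dataclass(frozen=True)
class StoppingPowerTable:
    """Tabulated LET on a strictly increasing energy grid.

    Interpolation between knots is log-log linear, the standard choice for
    stopping powers (smooth, positive, exact at the knots).
    """

    material: str
    energies: np.ndarray
    let_values: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=float)
        s = np.asarray(self.let_values, dtype=float)
        if e.ndim != 1 or e.shape != s.shape:
            raise ValueError("energies and let_values must be matching 1-D arrays")
        if not np.all(np.diff(e) > 0):
            raise ValueError("energy grid must be strictly increasing")
        if not np.all(s > 0):
            raise ValueError("LET values must be strictly positive")
        if e[0] > E_CUTOFF_KEV or e[-1] < 20000.0:
            raise ValueError("table must span at least [10 keV, 20000 keV]")
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "let_values", s)
        object.__setattr__(self, "_log_e", np.log(e))
        object.__setattr__(self, "_log_s", np.log(s))

    @property
    def e_min(self) -> float:
        return float(self.energies[0])

    @property
    def e_max(self) -> float:
        return float(self.energies[-1])

    def let(self, energy_kev):
        """LET at ``energy_kev`` (scalar or array), log-log interpolated."""
        e = np.asarray(energy_kev, dtype=float)
        if np.any(e <= 0) or np.any(e > self.e_max):
            raise ValueError(
                f"energy outside the stopping table support "
                f"[{self.e_min:g}, {self.e_max:g}] keV"
            )
        out = np.exp(np.interp(np.log(np.clip(e, self.e_min, None)), self._log_e, self._log_s))
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class MaterialModel:
    """A stopping medium: density plus a water LET table and a path scaling.

    ``water_equivalence_factor`` w converts a geometric path length t in this
    material into the water path length w*t that produces the same slowing.
    Water itself has w = 1.
    """

    name: str
    density: float  # kg/m^3
    table: StoppingPowerTable
    water_equivalence_factor: float = 1.0
    # fine-grid cumulative range/energy interpolants, built lazily
    _cache: dict = field(default_factory=dict, compare=False, repr=False)

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError("density must be positive")
        if self.water_equivalence_factor <= 0:
            raise ValueError("water_equivalence_factor must be positive")

    # -- range/energy interpolants (water path lengths) -------------------
    def _grids(self) -> tuple[np.ndarray, np.ndarray]:
        if "r" not in self._cache:
            e = np.geomspace(E_CUTOFF_KEV, self.table.e_max, 6000)
            inv = 1.0 / self.table.let(e)
            r = np.concatenate([[0.0], np.cumsum(np.diff(e) * 0.5 * (inv[1:] + inv[:-1]))])
            self._cache["e"] = e
            self._cache["r"] = r
        return self._cache["e"], self._cache["r"]

    def range_water(self, energy_kev):
        """CSDA range in *water path length* (um) from the cutoff energy."""
        e_grid, r_grid = self._grids()
        e = np.asarray(energy_kev, dtype=float)
        if np.any(e < 0):
            raise ValueError("energy must be non-negative")
        if np.any(e > self.table.e_max):
            raise ValueError(f"energy above table maximum {self.table.e_max:g} keV")
        out = np.interp(e, e_grid, r_grid)  # E <= cutoff -> 0
        return out if out.ndim else float(out)

    def energy_at_range(self, range_um):
        """Inverse of :meth:`range_water`; 0 below the cutoff range."""
        e_grid, r_grid = self._grids()
        r = np.asarray(range_um, dtype=float)
        out = np.interp(r, r_grid, e_grid)
        out = np.where(r <= 0.0, 0.0, out)
        return out if out.ndim else float(out)


_DEFAULT_E, _DEFAULT_S = _load_default_table()
WATER_TABLE = StoppingPowerTable("water", _DEFAULT_E, _DEFAULT_S)

WATER = MaterialModel("water", WATER_DENSITY_KG_M3, WATER_TABLE, 1.0)
#: Mylar as scaled water; the foil is only 1.4 um so a simple per-length
#: equivalence factor (default 1.2) captures the extra slowing.
MYLAR = MaterialModel("mylar", 1400.0, WATER_TABLE, 1.2)


def let_water(energy_kev):
    """LET of an alpha particle in liquid water (keV/um)."""
    return WATER_TABLE.let(energy_kev)


def csda_range(energy_kev, material: MaterialModel = WATER):
    """Continuous-slowing-down range (um of geometric path) in ``material``."""
    return material.range_water(energy_kev) / material.water_equivalence_factor


def residual_energy(energy_in_kev, thickness_um, material: MaterialModel = WATER):
    """Kinetic energy after traversing ``thickness_um`` of ``material``.

    Computed through the cumulative range: E_out = R^-1(R(E_in) - w*t), which
    makes the composition law residual(E, a+b) = residual(residual(E, a), b)
    hold to interpolation accuracy.  Returns 0 when the particle stops.
    """
    t = np.asarray(thickness_um, dtype=float)
    if np.any(t < 0):
        raise ValueError("thickness must be non-negative")
    e_in = np.asarray(energy_in_kev, dtype=float)
    r0 = material.range_water(e_in)
    out = material.energy_at_range(r0 - t * material.water_equivalence_factor)
    out = np.where(t == 0.0, e_in, out)  # exact identity at zero thickness
    return out if out.ndim else float(out)


def energy_deposited(energy_in_kev, chord_um, material: MaterialModel = WATER):
    """Energy (keV) deposited over a chord; the full energy if it stops."""
    return np.asarray(energy_in_kev, dtype=float) - residual_energy(
        energy_in_kev, chord_um, material
    )


def specific_energy_gy(energy_kev, volume_um3, density_kg_m3: float = WATER_DENSITY_KG_M3):
    """Specific energy z (Gy) from deposited energy and target volume."""
    mass_kg = volume_um3 * 1e-18 * density_kg_m3
    return np.asarray(energy_kev, dtype=float) * KEV_TO_J / mass_kg
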
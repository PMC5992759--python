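"""Nucleus specific-energy distributions.

The central object is the binned specific-energy distribution with an
explicit probability mass at exactly zero dose.  Three routes produce the
nucleus dose distribution (NDD) at a mean absorbed dose zbar:

* ``compute_shndd`` — the single-hit distribution (SHNDD) measured by
  tracing every track of a field through a voxelized cell at many random
  lateral placements; its mean q is the average dose of one traversal.
* ``analytic_ndd`` — the compound-Poisson construction: a Poisson number
  of hits (lambda = zbar/q) with i-fold self-convolutions of the SHNDD.
* ``mc_ndd`` — direct resampling of the measured field: per repetition,
  N = zbar/D_total * N_total tracks are drawn with replacement and their
  nucleus deposits summed.

All doses are Gy (J/kg), energies keV.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np
from scipy.fft import next_fast_len
from scipy.stats import poisson

from . import physics
from .cells import Label, LabelVolume, ray_segments
from .physics import MYLAR, WATER, specific_energy_gy
from .tracks import TrackField, total_dose

__all__ = [
    "DoseDistribution",
    "HitNumberModel",
    "poisson_pmf",
    "compute_shndd",
    "single_hit_deposits",
    "mean_energy_per_hit",
    "self_convolve",
    "analytic_ndd",
    "mc_ndd",
    "distribution_rmse",
    "kolmogorov_distance",
    "DistributionRMSE",
]


class DoseDistribution:
    """Probability density on a uniform specific-energy grid plus a point
    mass at z = 0 (the delta term for unhit nuclei).

    density integrates to 1 - zero_mass; the mean is the first moment of
    the binned density (bin centers as quadrature points).
    """

    def __init__(self, bin_edges, density, zero_mass: float = 0.0):
        edges = np.asarray(bin_edges, dtype=float)
        dens = np.asarray(density, dtype=float)
        if edges.ndim != 1 or len(edges) != len(dens) + 1:
            raise ValueError("need len(bin_edges) == len(density) + 1")
        widths = np.diff(edges)
        if not np.allclose(widths, widths[0], rtol=1e-9, atol=1e-12):
            raise ValueError("bin spacing must be uniform")
        if np.any(dens < -1e-12):
            raise ValueError("density must be non-negative")
        if not -1e-9 <= zero_mass <= 1 + 1e-9:
            raise ValueError("zero_mass must be a probability")
        self.bin_edges = edges
        self.density = np.clip(dens, 0.0, None)
        self.zero_mass = float(np.clip(zero_mass, 0.0, 1.0))
        total = self.zero_mass + float(np.sum(self.density) * widths[0])
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"distribution mass {total:.8f} is not 1")

    # -- geometry ---------------------------------------------------------
    @property
    def dz(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def pmf(self) -> np.ndarray:
        return self.density * self.dz

    def moment(self, k: int) -> float:
        return float(np.sum(self.pmf * self.centers**k))

    @property
    def mean(self) -> float:
        return self.moment(1)

    def laplace(self, alpha: float) -> float:
        """E[exp(-alpha z)], including the zero-dose mass."""
        return self.zero_mass + float(np.sum(self.pmf * np.exp(-alpha * self.centers)))

    def hit_cdf(self, z) -> np.ndarray:
        """CDF of the z > 0 part (zero_mass excluded), piecewise linear."""
        cum = np.concatenate([[0.0], np.cumsum(self.pmf)])
        return np.interp(z, self.bin_edges, cum)

    def cdf(self, z) -> np.ndarray:
        return np.where(np.asarray(z, float) >= 0, self.zero_mass + self.hit_cdf(z), 0.0)

    def rebin(self, bin_edges) -> "DoseDistribution":
        """Mass-conserving rebin onto another uniform grid (CDF resampling).

        Mass beyond the new grid is accumulated into the last bin so the
        distribution stays normalized.
        """
        edges = np.asarray(bin_edges, dtype=float)
        cdf = self.hit_cdf(edges)
        mass = np.diff(cdf)
        mass[-1] += (1.0 - self.zero_mass) - cdf[-1]
        return DoseDistribution(edges, mass / np.diff(edges), self.zero_mass)

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_samples(cls, samples, bins: int = 500, zero_mass: float = 0.0,
                     z_max: Optional[float] = None) -> "DoseDistribution":
        """Histogram positive dose samples; the hit part carries 1 - zero_mass."""
        s = np.asarray(samples, dtype=float)
        s = s[s > 0]
        if len(s) == 0:
            raise ValueError("no positive samples")
        z_max = float(z_max if z_max is not None else s.max() * (1 + 1e-9))
        edges = np.linspace(0.0, z_max, bins + 1)
        counts, _ = np.histogram(np.clip(s, None, z_max * (1 - 1e-12)), bins=edges)
        dens = counts / counts.sum() * (1.0 - zero_mass) / np.diff(edges)
        return cls(edges, dens, zero_mass)

    @classmethod
    def point_mass(cls, q: float, bins: int = 500) -> "DoseDistribution":
        """Degenerate single-hit distribution: all mass at exactly z = q.

        The grid is chosen so q falls exactly on a bin center, which keeps
        closed-form compound-Poisson checks exact.
        """
        if q <= 0:
            raise ValueError("q must be positive")
        k = bins // 2
        dz = q / (k + 0.5)
        edges = np.arange(bins + 1) * dz
        dens = np.zeros(bins)
        dens[k] = 1.0 / dz
        return cls(edges, dens)

    # -- I/O ---------------------------------------------------------------
    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# zero_mass={self.zero_mass!r}\n")
            fh.write(f"# mean_gy={self.mean!r}\n")
            fh.write(f"# bin_width_gy={self.dz!r}\n")
            fh.write("bin_center_gy\tdensity_per_gy\n")
            for c, d in zip(self.centers, self.density):
                fh.write(f"{c:.9g}\t{d:.9g}\n")

    @classmethod
    def from_tsv(cls, path) -> "DoseDistribution":
        meta = {}
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    k, _, v = line[1:].strip().partition("=")
                    try:
                        meta[k.strip()] = float(v)
                    except ValueError:
                        pass  # non-numeric metadata (command echo etc.)
                elif line.strip() and not line[0].isalpha():
                    rows.append([float(x) for x in line.split()])
        arr = np.asarray(rows)
        dz = meta.get("bin_width_gy", arr[1, 0] - arr[0, 0])
        # rebuild an exactly uniform grid from the first center (the stored
        # centers are rounded to the file's print precision)
        start = max(arr[0, 0] - dz / 2, 0.0)
        edges = start + np.arange(len(arr) + 1) * dz
        dens = arr[:, 1]
        zero = meta.get("zero_mass", 0.0)
        dens = dens / max(np.sum(dens) * dz / (1.0 - zero), 1e-300) if zero < 1 else dens
        return cls(edges, dens, zero)


@dataclass(frozen=True)
class HitNumberModel:
    """Poisson hit-number model with an explicit truncation order."""

    lam: float
    truncation: int
    tail_tol: float = 1e-9

    @classmethod
    def from_mean(cls, lam: float, tail_tol: float = 1e-9) -> "HitNumberModel":
        if lam < 0:
            raise ValueError("lambda must be non-negative")
        n = max(1, int(poisson.isf(tail_tol, lam)) if lam > 0 else 1)
        while poisson.sf(n, lam) > tail_tol:
            n += 1
        return cls(lam, n, tail_tol)


def poisson_pmf(i, lam) -> float:
    """P(i hits | mean lam); log-space evaluation, stable for large i."""
    i_arr = np.asarray(i)
    if np.any(i_arr < 0) or not np.issubdtype(i_arr.dtype, np.integer):
        raise ValueError("hit count i must be a non-negative integer")
    if np.any(np.asarray(lam) < 0):
        raise ValueError("lambda must be non-negative")
    out = poisson.pmf(i, lam)
    return float(out) if np.ndim(out) == 0 else out


# ------------------------------------------------- single-hit engine -----

def _deposits_for_placement(entries, dirs, energies, vol: LabelVolume,
                            mylar_thickness: float) -> np.ndarray:
    """Nucleus energy deposit (keV) of every track for one cell placement."""
    n = len(energies)
    dep = np.zeros(n)
    dz = dirs[:, 2]
    down = dz > 1e-9
    tau1 = np.where(down, mylar_thickness / np.clip(dz, 1e-9, None), np.inf)
    e1 = np.where(down, physics.residual_energy(energies, np.where(down, tau1, 0.0), MYLAR), 0.0)
    r1 = WATER.range_water(np.clip(e1, 0.0, None))
    # conservative lateral prefilter: can the ray touch the volume's xy box?
    lo = vol.origin[:2]
    hi = vol.origin[:2] + vol.size_um[:2]
    t_max = tau1 + r1
    for k in range(n):
        if not down[k] or e1[k] <= 0:
            continue
        x0, x1 = entries[k, 0], entries[k, 0] + dirs[k, 0] * t_max[k]
        y0, y1 = entries[k, 1], entries[k, 1] + dirs[k, 1] * t_max[k]
        if max(x0, x1) < lo[0] or min(x0, x1) > hi[0]:
            continue
        if max(y0, y1) < lo[1] or min(y0, y1) > hi[1]:
            continue
        t0, t1, lab = ray_segments(vol, entries[k], dirs[k], t_max=t_max[k])
        nuc = lab == int(Label.NUCLEUS)
        if not nuc.any():
            continue
        s0 = np.clip(t0[nuc] - tau1[k], 0.0, None)
        s1 = np.clip(t1[nuc] - tau1[k], 0.0, None)
        e_in = WATER.energy_at_range(r1[k] - s0)
        e_out = WATER.energy_at_range(r1[k] - s1)
        dep[k] = float(np.sum(e_in - e_out))
    return dep


def single_hit_deposits(field: TrackField, vol: LabelVolume, placements: int = 32,
                        seed: int | None = None, mylar_thickness: float = 1.4):
    """Per-(placement, track) nucleus deposits (keV) for random lateral
    placements of the cell in the field.  Returns an array of shape
    (placements, n_tracks); zeros are misses."""
    if field.n_total == 0:
        raise ValueError("track field is empty")
    if vol.count(Label.NUCLEUS) == 0:
        raise ValueError("cell has no nucleus voxels")
    rng = np.random.default_rng(seed)
    if field.extent is not None:
        ext = np.asarray(field.extent, float)
    else:
        ext = np.full(2, np.sqrt(field.area))
    span = np.clip(ext - vol.size_um[:2], 0.0, None)
    entries, dirs, energies = field.entries(), field.directions(), field.energies()
    out = np.zeros((placements, field.n_total))
    for p in range(placements):
        off = rng.uniform(0.0, 1.0, size=2) * span
        vol_p = vol.with_origin([off[0], off[1], mylar_thickness])
        out[p] = _deposits_for_placement(entries, dirs, energies, vol_p, mylar_thickness)
    return out


def compute_shndd(field: TrackField, vol: LabelVolume, placements: int = 32,
                  bins: int = 500, seed: int | None = None,
                  mylar_thickness: float = 1.4) -> DoseDistribution:
    """Single-hit nucleus dose distribution: specific energy of individual
    traversals, conditioned on a hit (zero_mass = 0); its mean is q."""
    dep = single_hit_deposits(field, vol, placements, seed, mylar_thickness)
    hits = dep[dep > 0]
    if hits.size == 0:
        raise ValueError(
            "no track hit the nucleus; increase placements or field density"
        )
    from .cells import nucleus_volume

    z = specific_energy_gy(hits, nucleus_volume(vol))
    return DoseDistribution.from_samples(z, bins=bins)


def mean_energy_per_hit(field: TrackField, volumes, placements: int = 8,
                        seed: int | None = None, mylar_thickness: float = 1.4) -> float:
    """Average energy (keV) deposited per nucleus traversal over a cell
    collection."""
    if isinstance(volumes, LabelVolume):
        volumes = [volumes]
    all_hits = []
    for j, vol in enumerate(volumes):
        dep = single_hit_deposits(field, vol, placements,
                                  None if seed is None else seed + j, mylar_thickness)
        all_hits.append(dep[dep > 0])
    hits = np.concatenate(all_hits)
    if hits.size == 0:
        raise ValueError("no hits over the collection")
    return float(hits.mean())


# -------------------------------------------- compound-Poisson engine ----

def _aligned_power(pmf: np.ndarray, i: int, n_fft: int) -> np.ndarray:
    """i-fold self-convolution of a bin-center pmf, re-aligned to the
    center lattice.  Sums of i centers sit at (m + i/2) dz; odd orders shift
    exactly, even orders split half/half between neighbours (mean exact)."""
    f = np.fft.rfft(pmf, n_fft)
    conv = np.fft.irfft(f**i, n_fft)
    conv = np.clip(conv, 0.0, None)
    out = np.zeros(n_fft)
    if i % 2 == 1:
        s = (i - 1) // 2
        out[s:] = conv[: n_fft - s]
    else:
        s = i // 2
        out[s - 1:] += 0.5 * conv[: n_fft - s + 1]
        out[s:] += 0.5 * conv[: n_fft - s]
    return out


def self_convolve(f1: DoseDistribution, i: int) -> DoseDistribution:
    """Distribution of the sum of i independent draws from f1."""
    if i < 1:
        raise ValueError("i must be >= 1")
    if f1.zero_mass > 1e-12:
        raise ValueError("self_convolve expects a hit-conditioned (zero_mass 0) input")
    if i == 1:
        return f1
    b = len(f1.density)
    n_fft = next_fast_len(i * b + i // 2 + 1)
    pmf = _aligned_power(f1.pmf, i, n_fft)
    pmf /= pmf.sum()
    edges = np.arange(n_fft + 1) * f1.dz
    return DoseDistribution(edges, pmf / f1.dz)


def analytic_ndd(f1: DoseDistribution, zbar: float, tail_tol: float = 1e-9) -> DoseDistribution:
    """Compound-Poisson nucleus dose distribution at mean absorbed dose zbar.

    f(z, zbar) = p(0, lam) delta(z) + sum_{i=1..N} p(i, lam) f^i(z) with
    lam = zbar / q, q the SHNDD mean, and N the smallest order whose
    neglected Poisson tail is below ``tail_tol``.
    """
    if zbar < 0:
        raise ValueError("zbar must be non-negative")
    q = f1.mean
    if q <= 0:
        raise ValueError("SHNDD mean must be positive")
    if zbar == 0:
        return DoseDistribution(f1.bin_edges, np.zeros_like(f1.density), 1.0)
    model = HitNumberModel.from_mean(zbar / q, tail_tol)
    lam, n_max = model.lam, model.truncation
    b = len(f1.density)
    if n_max > 400:
        return _analytic_ndd_large_lambda(f1, lam)
    n_fft = next_fast_len(n_max * b + n_max // 2 + 2)
    weights = poisson.pmf(np.arange(n_max + 1), lam)
    # accumulate sum_i p(i) f^i in the frequency domain; sums of i bin
    # centers sit at (m + i/2) dz, so each order is re-aligned to the center
    # lattice with a pure shift (odd i) or a half-bin linear split (even i),
    # both realized as phase factors
    f_hat = np.fft.rfft(f1.pmf, n_fft)
    w = np.exp(-2j * np.pi * np.arange(len(f_hat)) / n_fft)
    acc_hat = np.zeros_like(f_hat)
    power = np.ones_like(f_hat)
    shift = np.ones_like(f_hat)  # W^{(i-1)/2} for odd i, W^{i/2-1} for even
    half = 0.5 * (1.0 + w)
    for i in range(1, n_max + 1):
        power = power * f_hat
        if i % 2 == 1:
            if weights[i] > tail_tol * 1e-3:
                acc_hat += weights[i] * power * shift
        else:
            if weights[i] > tail_tol * 1e-3:
                acc_hat += weights[i] * power * shift * half
            shift = shift * w  # advance the integer part of the shift
    acc = np.clip(np.fft.irfft(acc_hat, n_fft), 0.0, None)
    edges = np.arange(n_fft + 1) * f1.dz
    return DoseDistribution(edges, acc / f1.dz, zero_mass=float(weights[0]))


def _analytic_ndd_large_lambda(f1: DoseDistribution, lam: float) -> DoseDistribution:
    """Many-hit regime: evaluate the full compound-Poisson characteristic
    function exp(lam (F - 1)) in closed form on a point lattice.

    The bin-center pmf is first split half/half onto the neighbouring
    lattice points k dz (mean-preserving); at the widths reached for
    lam >> 1 the half-bin smoothing this adds is negligible, and the cost
    no longer grows with lam.
    """
    dz = f1.dz
    pmf = f1.pmf
    lat = np.zeros(len(pmf) + 1)
    lat[:-1] += 0.5 * pmf
    lat[1:] += 0.5 * pmf
    q = f1.mean
    span = lam * q + 12.0 * np.sqrt(lam) * q + f1.bin_edges[-1]
    n_fft = next_fast_len(int(span / dz) + len(lat) + 8)
    f_hat = np.fft.rfft(lat, n_fft)
    acc_hat = np.exp(lam * (f_hat - 1.0)) - np.exp(-lam)
    acc = np.clip(np.fft.irfft(acc_hat, n_fft), 0.0, None)
    # lattice point k dz is reported as the bin [k dz, (k+1) dz): the
    # half-bin center offset this introduces is O(dz / (lam q)) relative,
    # far below the regime's statistical width
    return DoseDistribution(np.arange(n_fft + 1) * dz, acc / dz, np.exp(-lam))


# ---------------------------------------------------- Monte Carlo NDD ----

def mc_ndd(field: TrackField, vol: LabelVolume, zbar: float, reps: int = 10000,
           seed: int | None = None, placements: int = 64, bins: int = 500,
           poisson_n: bool = False, mylar_thickness: float = 1.4,
           deposit_matrix: np.ndarray | None = None,
           z_max: Optional[float] = None) -> DoseDistribution:
    """Monte Carlo NDD by resampling the measured field.

    Per repetition the cell is placed at a random lateral offset (drawn
    from ``placements`` precomputed offsets) and N = round(zbar/D_total *
    N_total) tracks are drawn uniformly with replacement; their nucleus
    specific energies are summed.  With ``poisson_n`` the per-repetition
    track count is Poisson-resampled around that mean instead.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    d_total = field.d_total if field.d_total is not None else total_dose(field)
    rng = np.random.default_rng(seed)
    if deposit_matrix is None:
        deposit_matrix = single_hit_deposits(
            field, vol, placements, rng.integers(2**31), mylar_thickness
        )
    from .cells import nucleus_volume

    zmat = specific_energy_gy(deposit_matrix, nucleus_volume(vol))
    n_pl, n_tr = zmat.shape
    n_mean = zbar / d_total * field.n_total
    if n_mean > 50 * field.n_total:
        import warnings

        warnings.warn("requested zbar far exceeds the dose carried by the field")
    sums = np.empty(reps)
    for r in range(reps):
        n_r = rng.poisson(n_mean) if poisson_n else int(round(n_mean))
        if n_r == 0:
            sums[r] = 0.0
            continue
        p = rng.integers(n_pl)
        idx = rng.integers(0, n_tr, size=n_r)
        sums[r] = zmat[p, idx].sum()
    zero_mass = float(np.mean(sums == 0.0))
    if zero_mass == 1.0:
        edges = np.linspace(0, max(zbar, 1e-6), bins + 1)
        return DoseDistribution(edges, np.zeros(bins), 1.0)
    return DoseDistribution.from_samples(
        sums[sums > 0], bins=bins, zero_mass=zero_mass, z_max=z_max
    )


# ----------------------------------------------------- comparison --------

class DistributionRMSE(NamedTuple):
    density: float  # RMSE of the binned densities (per Gy)
    zero_mass: float  # absolute difference of the zero-dose masses


def distribution_rmse(a: DoseDistribution, b: DoseDistribution) -> DistributionRMSE:
    """Root-mean-square difference of densities on ``a``'s grid; the
    zero-dose masses are compared separately."""
    b_on_a = b.rebin(a.bin_edges)
    rmse = float(np.sqrt(np.mean((a.density - b_on_a.density) ** 2)))
    return DistributionRMSE(rmse, abs(a.zero_mass - b.zero_mass))


def kolmogorov_distance(a: DoseDistribution, b: DoseDistribution) -> float:
    """sup |F_a - F_b| including the zero-dose point masses."""
    grid = np.union1d(a.bin_edges, b.bin_edges)
    fa = a.zero_mass + a.hit_cdf(grid)
    fb = b.zero_mass + b.hit_cdf(grid)
    # also compare at 0+ where the zero masses alone apply
    return float(max(np.max(np.abs(fa - fb)), abs(a.zero_mass - b.zero_mass)))
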
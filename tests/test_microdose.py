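"""Dose distributions: SHNDD computation, Poisson machinery, convolution,
the analytic compound-Poisson NDD and the Monte Carlo NDD."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alphamicro import cells, microdose as md, physics, tracks
from alphamicro.cells import nucleus_volume
from alphamicro.microdose import DoseDistribution
from alphamicro.tracks import AlphaTrack, TrackField

from ._oracles import sampled_label_lengths, stepper_residual


def _random_shndd(rng, bins=200):
    dens = rng.gamma(0.7, size=bins) * np.exp(-((np.arange(bins) - rng.uniform(20, 150)) ** 2) / 800)
    dens += 1e-9
    edges = np.linspace(0.0, rng.uniform(0.1, 0.6), bins + 1)
    dens /= dens.sum() * np.diff(edges)[0]
    return DoseDistribution(edges, dens)


class TestDoseDistribution:
    def test_mass_must_be_one(self):
        edges = np.linspace(0, 1, 11)
        with pytest.raises(ValueError, match="mass"):
            DoseDistribution(edges, np.full(10, 0.5))

    def test_point_mass_mean_exact(self):
        d = DoseDistribution.point_mass(0.1234)
        assert d.mean == pytest.approx(0.1234, rel=1e-12)

    def test_tsv_round_trip(self, tmp_path):
        d = _random_shndd(np.random.default_rng(0))
        path = tmp_path / "dist.tsv"
        d.to_tsv(path)
        back = DoseDistribution.from_tsv(path)
        assert back.mean == pytest.approx(d.mean, rel=1e-6)
        np.testing.assert_allclose(back.density, d.density, rtol=1e-6)

    def test_rebin_conserves_mass_and_mean(self):
        d = _random_shndd(np.random.default_rng(1))
        r = d.rebin(np.linspace(0, d.bin_edges[-1] * 1.1, 80))
        assert r.moment(0) == pytest.approx(d.moment(0), abs=1e-9)
        assert r.mean == pytest.approx(d.mean, rel=5e-3)


class TestPoisson:
    def test_zero_hits(self):
        assert md.poisson_pmf(0, 1.7) == pytest.approx(np.exp(-1.7))

    def test_closed_form_value(self):
        assert md.poisson_pmf(2, 1.0) == pytest.approx(0.18394, abs=1e-5)

    def test_truncation_captures_mass(self):
        model = md.HitNumberModel.from_mean(6.3)
        total = sum(md.poisson_pmf(i, 6.3) for i in range(model.truncation + 1))
        assert total > 1 - 1e-8

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            md.poisson_pmf(-1, 1.0)


class TestSelfConvolve:
    def test_identity(self):
        f1 = _random_shndd(np.random.default_rng(2))
        assert md.self_convolve(f1, 1) is f1

    def test_point_mass_translates(self):
        f1 = DoseDistribution.point_mass(0.05, bins=100)
        f3 = md.self_convolve(f1, 3)
        assert f3.mean == pytest.approx(0.15, rel=1e-12)
        assert f3.centers[np.argmax(f3.density)] == pytest.approx(0.15, abs=f3.dz)

    def test_three_fold_two_bin_enumeration(self):
        # mass 0.4 at z1 and 0.6 at z2; enumerate all 2^3 outcomes
        edges = np.linspace(0.0, 1.0, 11)
        dens = np.zeros(10)
        dens[2] = 0.4 / 0.1  # z1 = 0.25
        dens[5] = 0.6 / 0.1  # z2 = 0.55
        f1 = DoseDistribution(edges, dens)
        f3 = md.self_convolve(f1, 3)
        expected = {}
        for a in (0.25, 0.55):
            for b in (0.25, 0.55):
                for c in (0.25, 0.55):
                    p = np.prod([0.4 if v == 0.25 else 0.6 for v in (a, b, c)])
                    expected[round(a + b + c, 10)] = expected.get(round(a + b + c, 10), 0) + p
        for z, p in expected.items():
            k = int(round(z / f3.dz - 0.5))
            assert f3.pmf[k] == pytest.approx(p, abs=1e-9)

    def test_mean_scales_linearly(self):
        f1 = _random_shndd(np.random.default_rng(3))
        f4 = md.self_convolve(f1, 4)
        assert f4.mean == pytest.approx(4 * f1.mean, rel=1e-4)


class TestAnalyticNdd:
    def test_zero_mass_is_poisson_vacancy(self):
        f1 = _random_shndd(np.random.default_rng(4))
        zbar = 2.5 * f1.mean
        ndd = md.analytic_ndd(f1, zbar)
        assert ndd.zero_mass == pytest.approx(np.exp(-zbar / f1.mean), rel=1e-9)

    def test_mean_equals_zbar(self):
        f1 = _random_shndd(np.random.default_rng(5))
        ndd = md.analytic_ndd(f1, 0.42)
        assert ndd.mean == pytest.approx(0.42, rel=1e-3)

    def test_degenerate_reduces_to_poisson_lattice(self):
        q = 0.08
        f1 = DoseDistribution.point_mass(q, bins=200)
        ndd = md.analytic_ndd(f1, q)  # lambda = 1
        for i in range(1, 6):
            lo, hi = (i * q) - 1.5 * ndd.dz, (i * q) + 1.5 * ndd.dz
            sel = (ndd.centers > lo) & (ndd.centers < hi)
            assert ndd.pmf[sel].sum() == pytest.approx(
                md.poisson_pmf(i, 1.0), rel=1e-6
            )

    def test_zero_dose_is_pure_point_mass(self):
        f1 = _random_shndd(np.random.default_rng(6))
        ndd = md.analytic_ndd(f1, 0.0)
        assert ndd.zero_mass == 1.0
        assert ndd.moment(0) == 0.0

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), ratio=st.floats(0.1, 5.0))
    def test_normalization_and_mean_property(self, seed, ratio):
        f1 = _random_shndd(np.random.default_rng(seed))
        zbar = ratio * f1.mean
        ndd = md.analytic_ndd(f1, zbar)
        assert ndd.zero_mass + ndd.moment(0) == pytest.approx(1.0, abs=1e-6)
        assert ndd.mean == pytest.approx(zbar, rel=1e-3)


class TestShndd:
    def test_single_vertical_track_is_point_mass(self):
        # field extent equals the cell extent, so the placement is pinned
        vol = cells.generate_synthetic_cell(4.0, 0.5, (150.0, 150.0, 400.0), seed=1)
        sx, sy, _ = vol.size_um
        trk = AlphaTrack([sx / 2, sy / 2, 0.0], [0, 0, 1.0], 5486.0)
        fld = TrackField([trk], area=sx * sy, extent=(sx, sy))
        dist = md.compute_shndd(fld, vol, placements=3, seed=0)
        assert np.count_nonzero(dist.density) == 1
        e1 = stepper_residual(5486.0, 1.4 * 1.2)
        placed = vol.with_origin([0, 0, 1.4])
        chord = sampled_label_lengths(
            placed, [sx / 2, sy / 2, 0.0], [0, 0, 1.0], 30.0
        )[201]
        t0s, _, labs = cells.ray_segments(placed, [sx / 2, sy / 2, 0.0], [0, 0, 1.0])
        pre_nucleus = float(t0s[labs == 201].min()) - 1.4
        e_at_nucleus = stepper_residual(e1, pre_nucleus)
        dep = e_at_nucleus - stepper_residual(e_at_nucleus, chord)
        expected = dep * physics.KEV_TO_J / (nucleus_volume(vol) * 1e-18 * 1000.0)
        assert dist.mean == pytest.approx(expected, rel=2e-3)

    def test_density_normalized(self, small_field, flat_cell):
        dist = md.compute_shndd(small_field, flat_cell, placements=8, seed=1)
        assert dist.moment(0) == pytest.approx(1.0, abs=1e-9)
        assert dist.zero_mass == 0.0

    def test_error_when_nothing_hits(self, flat_cell):
        trk = AlphaTrack([1.0, 1.0, 0.0], [0, 0, 1.0], 5486.0)
        fld = TrackField([trk], area=1e8, extent=(10000.0, 10000.0))
        with pytest.raises(ValueError, match="placements"):
            md.compute_shndd(fld, flat_cell, placements=2, seed=0)


class TestMeanEnergyPerHit:
    def test_identical_cells_are_exchangeable(self, small_field, flat_cell):
        one = md.mean_energy_per_hit(small_field, flat_cell, placements=4, seed=9)
        two = md.mean_energy_per_hit(small_field, [flat_cell, flat_cell], placements=4, seed=9)
        assert two == pytest.approx(one, rel=0.15)

    def test_matches_enumeration_oracle(self, small_field):
        vol = cells.generate_synthetic_cell(4.0, 1.0, (300.0, 300.0, 500.0), seed=3)
        dep = md.single_hit_deposits(small_field, vol, placements=2, seed=12)
        got = dep[dep > 0]
        # independent re-computation: dense sampling + explicit stepping
        entries, dirs, energies = (
            small_field.entries(), small_field.directions(), small_field.energies(),
        )
        rng = np.random.default_rng(12)
        ext = np.asarray(small_field.extent)
        span = np.clip(ext - vol.size_um[:2], 0.0, None)
        ref = []
        for p in range(2):
            off = rng.uniform(0.0, 1.0, size=2) * span
            vp = vol.with_origin([off[0], off[1], 1.4])
            for k in range(small_field.n_total):
                if dirs[k, 2] <= 1e-9:
                    continue
                tau1 = 1.4 / dirs[k, 2]
                e1 = stepper_residual(energies[k], tau1 * 1.2, step_um=2e-3)
                if e1 <= 0:
                    continue
                # walk nucleus segments with the stepper
                t0s, t1s, labs = cells.ray_segments(vp, entries[k], dirs[k])
                e = e1
                t_prev = tau1
                dep_k = 0.0
                for t0, t1, lab in zip(t0s, t1s, labs):
                    if t0 < tau1:
                        continue
                    e = stepper_residual(e, t0 - t_prev, step_um=2e-3) if t0 > t_prev else e
                    e_out = stepper_residual(e, t1 - t0, step_um=2e-3)
                    if lab == 201:
                        dep_k += e - e_out
                    e, t_prev = e_out, t1
                    if e <= 0:
                        break
                if dep_k > 0:
                    ref.append(dep_k)
        ref = np.asarray(ref)
        assert len(ref) == len(got)
        assert np.mean(got) == pytest.approx(np.mean(ref), rel=0.01)


class TestMcNdd:
    def test_zero_mass_matches_poisson_prediction(self, small_field, flat_cell):
        dep = md.single_hit_deposits(small_field, flat_cell, placements=16, seed=31)
        z = physics.specific_energy_gy(dep[dep > 0], nucleus_volume(flat_cell))
        q = z.mean()
        zbar = 1.2 * q
        reps = 10000
        mc = md.mc_ndd(small_field, flat_cell, zbar, reps=reps, seed=32,
                       deposit_matrix=dep)
        lam = zbar / q
        p0 = np.exp(-lam)
        # exact finite-sampling prediction: averaged per-placement vacancy
        n_draw = int(round(zbar / small_field.d_total * small_field.n_total))
        h_p = (dep > 0).mean(axis=1)
        p0_exact = np.mean((1.0 - h_p) ** n_draw)
        se = np.sqrt(p0_exact * (1 - p0_exact) / reps)
        assert abs(mc.zero_mass - p0_exact) < 3 * se
        # and the Poisson limit is close to the exact prediction
        assert p0_exact == pytest.approx(p0, rel=0.1)

    def test_dose_scaling_via_track_count(self, small_field, flat_cell):
        # zbar = d_total resamples exactly n_total tracks per repetition
        dep = md.single_hit_deposits(small_field, flat_cell, placements=4, seed=41)
        mc = md.mc_ndd(small_field, flat_cell, small_field.d_total, reps=300,
                       seed=42, deposit_matrix=dep)
        assert mc.mean == pytest.approx(small_field.d_total, rel=0.15)


class TestComparison:
    def test_rmse_identical_is_zero(self):
        d = _random_shndd(np.random.default_rng(7))
        r = md.distribution_rmse(d, d)
        assert r.density == pytest.approx(0.0, abs=1e-10)
        assert r.zero_mass == 0.0

    def test_rmse_symmetry_on_common_grid(self):
        rng = np.random.default_rng(8)
        a, b = _random_shndd(rng), _random_shndd(rng)
        b = b.rebin(a.bin_edges)
        assert md.distribution_rmse(a, b).density == pytest.approx(
            md.distribution_rmse(b, a).density
        )

    def test_rmse_hand_computed_three_bins(self):
        edges = np.array([0.0, 1.0, 2.0, 3.0])
        a = DoseDistribution(edges, np.array([0.5, 0.3, 0.2]))
        b = DoseDistribution(edges, np.array([0.2, 0.5, 0.3]))
        expected = np.sqrt((0.3**2 + 0.2**2 + 0.1**2) / 3)
        assert md.distribution_rmse(a, b).density == pytest.approx(expected)

    def test_kolmogorov_distance_zero_and_positive(self):
        d = _random_shndd(np.random.default_rng(9))
        assert md.kolmogorov_distance(d, d) == 0.0
        shifted = DoseDistribution(d.bin_edges + 0.0, np.roll(d.density, 5))
        assert md.kolmogorov_distance(d, shifted) > 0.0
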
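"""Simulator: displacement law, photophysics, misregistration, determinism."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from paintspt.simulate import (DyeKinetics, PaintKinetics, SimulationConfig,
                               apply_misregistration, paint_occupancy_trace,
                               simulate_membrane, singledye_visibility_trace)


def _always_visible(**kw):
    kw.setdefault("label_model", "single_dye")
    kw.setdefault("photophysics", DyeKinetics(k_bleach_dye=0.0))
    return SimulationConfig(**kw)


class TestSimulateMembrane:
    def test_zero_density_gives_empty_outputs(self):
        cfg = _always_visible(fov_side=10.0, n_frames=5,
                              density_per_channel=0.0, seed=0)
        truth, l1, l2 = simulate_membrane(cfg)
        assert truth.n_molecules == 0
        assert len(l1) == 0 and len(l2) == 0

    def test_frozen_system_reproduces_initial_positions(self):
        cfg = _always_visible(fov_side=10.0, n_frames=20,
                              density_per_channel=0.2, D_mono=0.0,
                              sigma_loc=0.0, sigma_reg_radial=0.0, seed=1)
        truth, l1, l2 = simulate_membrane(cfg)
        for df in (l1, l2):
            for tid, sub in df.groupby("truth_id"):
                p0 = truth.positions[tid, 0]
                assert np.allclose(sub[["x", "y"]].to_numpy(), p0)

    @pytest.mark.parametrize("D,dt", [(0.1, 0.08), (0.5, 0.04)])
    def test_step_variance_matches_2Ddt_per_axis(self, D, dt):
        """Per-frame Gaussian steps have per-axis variance 2 D dt; the mean
        squared 2D step is 4 D dt (here with a large FOV so reflections are
        irrelevant)."""
        cfg = _always_visible(fov_side=200.0, n_frames=101, dt=dt,
                              density_per_channel=100 / 200 ** 2, D_mono=D,
                              sigma_loc=0.0, sigma_reg_radial=0.0, seed=2)
        truth, _, _ = simulate_membrane(cfg)
        steps = np.diff(truth.positions, axis=1)
        sq = (steps ** 2).sum(axis=2).ravel()
        expected = 4 * D * dt
        se = sq.std(ddof=1) / math.sqrt(sq.size)
        assert abs(sq.mean() - expected) < 3 * se

    def test_molecule_count_conserved_and_visibility_bounds(self):
        cfg = SimulationConfig(fov_side=15.0, n_frames=50,
                               density_per_channel=0.1, seed=3)
        truth, l1, l2 = simulate_membrane(cfg)
        n = truth.n_molecules
        assert truth.positions.shape == (n, 50, 2)
        per_frame = l1.groupby("frame").size()
        assert (per_frame <= (truth.channel == 1).sum()).all()
        assert np.all(truth.positions >= 0)
        assert np.all(truth.positions <= cfg.fov_side)

    def test_identical_seed_bitwise_identical(self):
        cfg = dict(fov_side=12.0, n_frames=30, density_per_channel=0.1,
                   dimer_fraction=0.4, seed=7)
        out1 = simulate_membrane(SimulationConfig(**cfg))
        out2 = simulate_membrane(SimulationConfig(**cfg))
        assert np.array_equal(out1[0].positions, out2[0].positions)
        for a, b in zip(out1[1:], out2[1:]):
            assert a.equals(b)

    def test_static_dimers_share_positions(self):
        cfg = _always_visible(fov_side=12.0, n_frames=20,
                              density_per_channel=0.2, dimer_fraction=0.5,
                              seed=4)
        truth, _, _ = simulate_membrane(cfg)
        for i in np.flatnonzero(truth.partner >= 0):
            j = truth.partner[i]
            assert truth.partner[j] == i
            assert truth.channel[i] != truth.channel[j]
            assert np.allclose(truth.positions[i], truth.positions[j])

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(fov_side=-1.0).validate()
        with pytest.raises(ValueError):
            SimulationConfig(dimer_slowdown=1.2).validate()
        with pytest.raises(ValueError):
            SimulationConfig(D_mono=float("nan")).validate()


class TestPaintPhotophysics:
    def test_no_binding_gives_all_zero_trace(self):
        kin = PaintKinetics(k_on=0.0)
        tr = paint_occupancy_trace(kin, duration=10.0, dt=0.1, seed=0,
                                   initial="empty")
        assert np.all(tr == 0)

    def test_stationary_occupancy_binomial_law(self):
        """With no bleaching each site is an independent two-state process
        with on-fraction b/(b+k_off); time-averaged occupancy follows
        Binomial(n_sites, 1/6) for b=0.1, k_off=0.5."""
        kin = PaintKinetics(n_sites=9, k_on=1.0, c_imager=0.1, k_off=0.5,
                            k_bleach=0.0)
        # sample every 20 s (>> relaxation time 1/(b+k_off) ~ 1.7 s)
        tr = paint_occupancy_trace(kin, duration=60000.0, dt=20.0, seed=5)
        p = 1.0 / 6.0
        assert abs(tr.mean() - 9 * p) < 4 * tr.std(ddof=1) / math.sqrt(tr.size)
        assert abs((tr > 0).mean() - (1 - (1 - p) ** 9)) < 0.02
        # chi-square against the binomial pmf (tail bins merged)
        from scipy import stats
        k = np.arange(10)
        pmf = stats.binom.pmf(k, 9, p)
        obs = np.bincount(tr, minlength=10)[:10].astype(float)
        cut = 5  # merge sparse tail
        obs_m = np.append(obs[:cut], obs[cut:].sum())
        pmf_m = np.append(pmf[:cut], pmf[cut:].sum())
        chi2, pval = stats.chisquare(obs_m, pmf_m / pmf_m.sum() * obs_m.sum())
        assert pval > 1e-3

    def test_bleached_imagers_block_sites_until_unbinding(self):
        """With heavy bleaching and slow unbinding the bright fraction drops
        below the bleach-free stationary value."""
        kin_nb = PaintKinetics(n_sites=1, k_on=1.0, c_imager=0.5, k_off=0.2,
                               k_bleach=0.0)
        kin_bl = PaintKinetics(n_sites=1, k_on=1.0, c_imager=0.5, k_off=0.2,
                               k_bleach=2.0)
        assert kin_bl.stationary_site_probs()[1] < kin_nb.stationary_site_probs()[1]
        tr = paint_occupancy_trace(kin_bl, duration=20000.0, dt=5.0, seed=6)
        expect = kin_bl.stationary_site_probs()[1]
        assert abs((tr > 0).mean() - expect) < 0.02


class TestSingleDye:
    def test_no_bleaching_always_visible(self):
        tr = singledye_visibility_trace(DyeKinetics(0.0), 10.0, 0.1, seed=0)
        assert np.all(tr == 1)

    def test_all_visible_at_time_zero_and_exponential_survival(self):
        kin = DyeKinetics(k_bleach_dye=0.1)
        n = 10_000
        rng = np.random.default_rng(8)
        traces = np.array([singledye_visibility_trace(kin, 12.0, 1.0, seed=rng)
                           for _ in range(n)])
        assert traces[:, 0].sum() == n  # all visible at t=0
        frac10 = traces[:, 10].mean()
        expect = math.exp(-0.1 * 10)
        se = math.sqrt(expect * (1 - expect) / n)
        assert abs(frac10 - expect) < 4 * se


class TestMisregistration:
    def test_identity_no_noise_is_exact(self):
        pts = np.array([[1.0, 2.0], [3.0, 4.0]])
        out = apply_misregistration(pts, None, 0.0)
        assert np.array_equal(out, pts)

    @settings(max_examples=20, deadline=None)
    @given(st.floats(-1, 1), st.floats(-1, 1))
    def test_pure_shift_adds_exactly(self, sx, sy):
        pts = np.array([[0.5, 0.5], [2.0, 7.0]])
        out = apply_misregistration(pts, (np.eye(2), np.array([sx, sy])), 0.0)
        assert np.allclose(out, pts + np.array([sx, sy]), atol=1e-12)

    def test_rms_radial_error_matches_sigma(self):
        rng = np.random.default_rng(9)
        pts = np.zeros((100_000, 2))
        out = apply_misregistration(pts, None, 0.032, rng=rng)
        rms = math.sqrt((out ** 2).sum(axis=1).mean())
        assert abs(rms - 0.032) < 0.0005

    def test_singular_transform_rejected(self):
        with pytest.raises(ValueError):
            apply_misregistration(np.zeros((3, 2)),
                                  (np.zeros((2, 2)), np.zeros(2)), 0.0)
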
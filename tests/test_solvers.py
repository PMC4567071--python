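"""Outer reconstruction loops: cost, FBS, MM and TV baselines."""

import numpy as np
import pytest

import hdtv2 as h
from hdtv2.functional import hdtv2_value_directional
from hdtv2.linops import FourierMask, Measurement
from hdtv2.solvers import SolverConfig, cost, tv_cost


@pytest.fixture(scope="module")
def cs_instance():
    """One seeded 64x64 compressive-sensing instance: 30% sampling, 30 dB."""
    f = h.make_phantom("piecewise_linear", 64, 64, seed=3)
    mask = h.variable_density_mask(64, 64, 0.3, seed=4)
    g = h.simulate_measurement(f, mask, snr_db=30.0, seed=5)
    return f, mask, g


class TestCost:
    def test_zero_everything(self):
        mask = FourierMask(np.ones((8, 8), dtype=bool))
        g = Measurement(np.zeros(64, dtype=complex))
        assert cost(np.zeros((8, 8)), g, mask, lam=1.0) == 0.0

    def test_exact_data_no_regularization(self, rng):
        f = rng.standard_normal((8, 8))
        mask = FourierMask(np.ones((8, 8), dtype=bool))
        g = h.forward_model(f, mask)
        assert cost(f, g, mask, lam=0.0) == pytest.approx(0.0, abs=1e-20)

    def test_matches_directional_oracle(self, rng):
        f = rng.standard_normal((8, 8))
        mask = FourierMask(np.ones((8, 8), dtype=bool))
        g = Measurement(rng.standard_normal(64) + 1j * rng.standard_normal(64))
        lam = 0.37
        resid = h.forward_model(f, mask).data - g.data
        expected = 0.5 * float(np.vdot(resid, resid).real) + lam * hdtv2_value_directional(f)
        assert cost(f, g, mask, lam) == pytest.approx(expected, rel=1e-8)

    def test_negative_lambda_rejected(self, rng):
        mask = FourierMask(np.ones((8, 8), dtype=bool))
        with pytest.raises(ValueError):
            cost(np.zeros((8, 8)), Measurement(np.zeros(64)), mask, lam=-1.0)

    def test_coercive_direction_with_dc_sampled(self, cs_instance):
        # adding a constant moves the DC measurement, so cost strictly increases
        f, mask, g = cs_instance
        cfg = SolverConfig(lam=0.01, max_outer=30, inner_iters=15)
        recon, _ = h.fbs_reconstruct(g, mask, cfg)
        base = cost(recon, g, mask, cfg.lam)
        for c in (0.5, 1.0, 2.0):
            assert cost(recon + c, g, mask, cfg.lam) > base


class TestSolverConfig:
    def test_invalid_tau_rejected(self):
        for tau in (0.0, -0.5, 2.0, 2.5):
            with pytest.raises(ValueError):
                SolverConfig(lam=0.1, tau=tau)

    def test_alpha_propagates_to_prox(self):
        cfg = SolverConfig(lam=0.4, tau=0.5)
        assert cfg.prox_config().alpha == pytest.approx(0.2)


class TestFBS:
    def test_exact_recovery_full_mask_no_regularization(self, rng):
        f = rng.uniform(0.1, 0.9, size=(16, 16))
        mask = FourierMask(np.ones((16, 16), dtype=bool))
        g = h.forward_model(f, mask)
        cfg = SolverConfig(lam=0.0, tau=1.0, max_outer=5, tol=0.0)
        recon, _ = h.fbs_reconstruct(g, mask, cfg)
        assert np.allclose(recon, f, atol=1e-10)

    def test_improves_on_zero_filled_initializer(self, cs_instance):
        f, mask, g = cs_instance
        zf = np.clip(h.forward_adjoint(g, mask), 0.0, 1.0)
        cfg = SolverConfig(lam=0.01, tau=1.0, max_outer=100, inner_iters=15, tol=1e-5)
        recon, trace = h.fbs_reconstruct(g, mask, cfg, f_ref=f)
        assert trace.psnr[-1] > h.psnr(f, zf)

    def test_cost_nonincreasing_with_accurate_prox(self, cs_instance):
        f, mask, g = cs_instance
        cfg = SolverConfig(lam=0.01, tau=1.0, max_outer=60, inner_iters=100, tol=0.0)
        _, trace = h.fbs_reconstruct(g, mask, cfg)
        c = np.array(trace.cost)
        assert np.all(np.diff(c) <= 1e-5 * c[0])

    def test_residual_decays_and_fixed_point(self, cs_instance):
        f, mask, g = cs_instance
        cfg = SolverConfig(lam=0.01, tau=1.0, max_outer=400, inner_iters=100,
                           tol=1e-5)
        recon, trace = h.fbs_reconstruct(g, mask, cfg)
        assert trace.residual[-1] < 1e-5
        # one more outer iteration (same operator T) barely moves the image
        cfg2 = SolverConfig(lam=0.01, tau=1.0, max_outer=1, inner_iters=100, tol=0.0)
        z = recon - cfg2.tau * (h.forward_adjoint(h.forward_model(recon, mask), mask)
                                - h.forward_adjoint(g, mask))
        from hdtv2.prox import prox_hdtv2
        f_next, _ = prox_hdtv2(z, cfg2.prox_config())
        assert np.linalg.norm(f_next - recon) / np.linalg.norm(recon) < 1e-4

    def test_trace_lengths_consistent(self, cs_instance):
        f, mask, g = cs_instance
        cfg = SolverConfig(lam=0.01, max_outer=10, tol=0.0)
        _, trace = h.fbs_reconstruct(g, mask, cfg, f_ref=f)
        assert trace.iterations == 10
        df = trace.to_dataframe()
        assert list(df.columns) == ["iteration", "cost", "residual", "psnr_db",
                                    "relative_error"]
        assert len(df) == 10

    def test_regularization_monotone_in_lambda(self, cs_instance):
        # stronger λ yields reconstructions with smaller HDTV2 value
        f, mask, g = cs_instance
        values = []
        for lam in (1e-3, 1e-2, 1e-1):
            cfg = SolverConfig(lam=lam, max_outer=60, inner_iters=30, tol=1e-5)
            recon, _ = h.fbs_reconstruct(g, mask, cfg)
            values.append(h.hdtv2_value_weighted(recon))
        assert values[0] >= values[1] >= values[2]


class TestMM:
    def test_lambda_zero_full_mask_is_zero_filled(self, rng):
        f = rng.uniform(0.1, 0.9, size=(16, 16))
        mask = FourierMask(np.ones((16, 16), dtype=bool))
        g = h.forward_model(f, mask)
        cfg = SolverConfig(lam=0.0, max_outer=5)
        recon, trace = h.mm_reconstruct(g, mask, cfg)
        assert np.allclose(recon, f, atol=1e-8)
        assert trace.iterations == 1

    def test_flat_pixel_weights_are_finite(self):
        # at G2 = 0 the reweighting is C2/(2√ε): the guard keeps it finite
        from hdtv2.functional import build_C2
        eps = 1e-8
        w = build_C2(360) / (2.0 * np.sqrt(0.0 + eps))
        assert np.isfinite(w).all()

    def test_invalid_smoothing_rejected(self, cs_instance):
        _, mask, g = cs_instance
        with pytest.raises(ValueError):
            h.mm_reconstruct(g, mask, SolverConfig(lam=0.01), smoothing_eps=0.0)

    def test_cost_trace_decreases(self, cs_instance):
        f, mask, g = cs_instance
        cfg = SolverConfig(lam=0.01, max_outer=20, tol=0.0)
        _, trace = h.mm_reconstruct(g, mask, cfg)
        c = np.array(trace.cost)
        assert c[-1] < c[0]

    def test_fbs_reaches_lower_cost_at_matched_outer_iterations(self, cs_instance):
        f, mask, g = cs_instance
        cfg = SolverConfig(lam=0.01, tau=1.0, max_outer=200, inner_iters=15,
                           tol=0.0, warm_start=True)
        _, tr_fbs = h.fbs_reconstruct(g, mask, cfg)
        _, tr_mm = h.mm_reconstruct(g, mask, cfg)
        assert tr_fbs.cost[-1] < tr_mm.cost[-1]


class TestTVFISTA:
    def test_lambda_zero_full_mask_is_zero_filled(self, rng):
        f = rng.uniform(0.1, 0.9, size=(16, 16))
        mask = FourierMask(np.ones((16, 16), dtype=bool))
        g = h.forward_model(f, mask)
        cfg = SolverConfig(lam=0.0, max_outer=5, tol=0.0)
        recon, _ = h.tv_fista_reconstruct(g, mask, cfg)
        assert np.allclose(recon, f, atol=1e-10)

    def test_tv_cost_monotone(self, cs_instance):
        f, mask, g = cs_instance
        cfg = SolverConfig(lam=0.005, max_outer=60, inner_iters=15, tol=0.0)
        _, trace = h.tv_fista_reconstruct(g, mask, cfg)
        assert np.all(np.diff(trace.cost) <= 1e-12)

    def test_hdtv2_beats_tv_on_piecewise_linear_phantom(self, cs_instance):
        # the staircase-avoidance ordering, each method at its best λ
        f, mask, g = cs_instance
        grid = (1e-3, 3e-3, 1e-2, 3e-2)

        def best(method):
            scores = []
            for lam in grid:
                cfg = SolverConfig(lam=lam, max_outer=100, inner_iters=15,
                                   tol=1e-5, warm_start=True)
                _, tr = method(g, mask, cfg, f_ref=f)
                scores.append(tr.psnr[-1])
            return max(scores)

        assert best(h.fbs_reconstruct) >= best(h.tv_fista_reconstruct)
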
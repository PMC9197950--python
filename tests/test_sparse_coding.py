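import numpy as np
import pytest

from conftest import cd_lasso_oracle, lasso_objective_oracle, quiet_config
from funduschange.dictionary import PatchGeometry
from funduschange.image_io import as_pair
from funduschange.sparse_coding import (lasso_objective,
                                        reconstruct_background,
                                        reconstruct_patch_background,
                                        solve_lasso)
from funduschange.synthetic import generate_background


class TestSolveLasso:
    def test_zero_signal(self, rng):
        D = rng.normal(size=(9, 3))
        code = solve_lasso(np.zeros(9), D, 0.5)
        assert np.allclose(code.alpha, 0) and code.objective == 0
        assert code.nnz == 0

    @pytest.mark.parametrize("c,lam", [
        (1.0, 0.1), (-0.7, 0.05), (2.5, 1.0), (0.01, 5.0), (-0.3, 0.0),
    ])
    def test_single_atom_soft_threshold_closed_form(self, rng, c, lam):
        d = rng.normal(size=12)
        x = c * d
        code = solve_lasso(x, d[:, None], lam)
        expected = np.sign(c) * max(abs(c) - lam / (2 * d @ d), 0.0)
        assert np.allclose(code.alpha[0], expected, atol=1e-12)

    def test_matches_coordinate_descent_oracle(self, rng):
        for _ in range(10):
            D = rng.normal(size=(9, 3))
            x = rng.normal(size=9)
            lam = 0.1
            code = solve_lasso(x, D, lam)
            a_star = cd_lasso_oracle(x, D, lam)
            assert abs(code.objective
                       - lasso_objective_oracle(x, D, a_star, lam)) < 1e-8

    def test_zero_dictionary_returns_zero(self):
        x = np.ones(4)
        code = solve_lasso(x, np.zeros((4, 2)), 0.1)
        assert np.allclose(code.alpha, 0)
        assert code.objective == pytest.approx(4.0)

    def test_objective_never_exceeds_zero_vector(self, rng):
        # degenerate collinear dictionary (duplicated + zero atoms)
        d = rng.normal(size=10)
        D = np.column_stack([d, d, np.zeros(10), 2 * d])
        code = solve_lasso(d * 3, D, 1e-6)
        assert code.objective <= float(9 * d @ d) + 1e-12

    def test_lambda_monotonicity(self, rng):
        D = rng.normal(size=(16, 6))
        x = rng.normal(size=16)
        nnzs, l1s = [], []
        for lam in [0.01, 0.1, 0.5, 2.0, 10.0]:
            code = solve_lasso(x, D, lam)
            nnzs.append(code.nnz)
            l1s.append(np.abs(code.alpha).sum())
        assert all(a >= b for a, b in zip(nnzs, nnzs[1:]))
        assert all(a >= b - 1e-10 for a, b in zip(l1s, l1s[1:]))

    def test_lambda_zero_is_least_squares_projection(self, rng):
        D = rng.normal(size=(12, 4))
        x = rng.normal(size=12)
        recon = reconstruct_patch_background(x, D, 0.0)
        proj = D @ np.linalg.lstsq(D, x, rcond=None)[0]
        assert np.allclose(recon, proj, atol=1e-6)

    def test_optimality_against_random_perturbations(self, rng):
        D = rng.normal(size=(20, 8))
        x = rng.normal(size=20)
        lam = 0.3
        code = solve_lasso(x, D, lam)
        for _ in range(2000):
            perturbed = code.alpha + rng.normal(scale=1e-3, size=8)
            assert lasso_objective(x, D, perturbed, lam) >= code.objective - 1e-12

    def test_negative_lambda_rejected(self, rng):
        with pytest.raises(ValueError):
            solve_lasso(np.ones(3), rng.normal(size=(3, 2)), -1.0)


class TestReconstructPatch:
    def test_exactly_representable_atom(self, rng):
        D = rng.normal(size=(25, 5))
        x = D[:, 2].copy()
        recon = reconstruct_patch_background(x, D, 1e-9)
        assert np.abs(recon - x).max() < 1e-6

    def test_orthogonal_signal_reconstructs_to_zero(self, rng):
        M = rng.normal(size=(8, 8))
        Q, _ = np.linalg.qr(M)
        D = Q[:, :3]          # atoms span a 3-dim subspace
        x = Q[:, 5]           # orthogonal to every atom
        recon = reconstruct_patch_background(x, D, 0.01)
        assert np.abs(recon).max() < 1e-10

    def test_spike_energy_stays_in_residual(self, rng):
        d = rng.normal(size=25)
        spike = np.zeros(25)
        spike[7] = 2.0
        x = d + spike
        recon = reconstruct_patch_background(x, d[:, None], 1e-6)
        resid = x - recon
        assert resid[7] ** 2 >= 0.5 * (resid @ resid)


class TestReconstructBackground:
    geometry = PatchGeometry(patch_size=9, window_size=18, grid=3)

    def _reference(self):
        return generate_background(quiet_config(height=80, width=80, seed=3))

    def test_identity_pair_reconstructs_current(self):
        ref = self._reference()
        pair = as_pair(ref, ref.copy())
        bg = reconstruct_background(pair, self.geometry)
        assert np.mean(np.abs(bg.pixels - pair.current)) < 1e-3

    def test_global_affine_change_absorbed(self):
        ref = self._reference()
        cur = 1.2 * ref + 0.05
        bg = reconstruct_background(as_pair(ref, cur), self.geometry)
        assert np.mean(np.abs(bg.pixels - cur)) < 5e-3

    def test_full_coverage_with_tiling_stride(self):
        ref = self._reference()
        bg = reconstruct_background(as_pair(ref, ref), self.geometry,
                                    stride=self.geometry.patch_size)
        assert bg.coverage.min() >= 1

    def test_overlapping_stride_increases_coverage(self):
        ref = self._reference()
        bg = reconstruct_background(as_pair(ref, ref), self.geometry, stride=5)
        assert bg.coverage.max() > 1
        assert bg.coverage.min() >= 1

    def test_auto_lambda_is_inverse_pixel_count(self):
        # too-small image for the default 25x25 patch must be rejected
        ref = np.random.default_rng(0).random((20, 20))
        with pytest.raises(ValueError, match="patch"):
            reconstruct_background(as_pair(ref, ref))

    def test_illumination_robustness_headroom(self):
        # residual under a pure smooth gain stays below the smallest lesion
        # contrast used in the lesion-recovery scenarios (0.3 * 0.5 blend)
        from funduschange.synthetic import SimConfig, generate_pair
        sp = generate_pair(SimConfig(height=96, width=96, seed=5, n_lesions=0,
                                     noise_sigma=0.0, jitter=0.0))
        bg = reconstruct_background(sp.pair, self.geometry)
        p99 = np.quantile(np.abs(sp.pair.current - bg.pixels), 0.99)
        assert p99 < 0.15
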
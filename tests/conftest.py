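import numpy as np
import pytest

from funduschange.dictionary import PatchGeometry
from funduschange.synthetic import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_geometry():
    """Compact dictionary geometry for fast end-to-end tests."""
    return PatchGeometry(patch_size=9, window_size=18, grid=3)


def quiet_config(**kw):
    """SimConfig with every nuisance (illumination, noise, jitter) off."""
    base = dict(n_lesions=0, gain_amplitude=0.0, bias_amplitude=0.0,
                bump_count=0, noise_sigma=0.0, jitter=0.0)
    base.update(kw)
    return SimConfig(**base)


@pytest.fixture
def quiet_cfg():
    return quiet_config


def cd_lasso_oracle(x, D, lam, max_sweeps=20000, tol=1e-13):
    """Independent coordinate-descent solver for the patch lasso objective

        f(a) = ||x - D a||_2^2 + lam * ||a||_1.

    The stationarity update for coordinate j is
    a_j <- soft(d_j . (x - D a + d_j a_j), lam/2) / ||d_j||^2.
    Written directly from the objective; shares no code with the package.
    """
    x = np.asarray(x, float).ravel()
    D = np.asarray(D, float)
    q = D.shape[1]
    G = D.T @ D
    b = D.T @ x
    diag = np.diag(G).copy()
    a = np.zeros(q)
    half = lam / 2.0
    for _ in range(max_sweeps):
        delta = 0.0
        for j in range(q):
            if diag[j] == 0:
                continue
            rho = b[j] - G[j] @ a + diag[j] * a[j]
            new = np.sign(rho) * max(abs(rho) - half, 0.0) / diag[j]
            delta = max(delta, abs(new - a[j]))
            a[j] = new
        if delta < tol:
            break
    return a


def lasso_objective_oracle(x, D, a, lam):
    r = np.asarray(x, float).ravel() - np.asarray(D, float) @ a
    return float(r @ r + lam * np.abs(a).sum())


def auc_pair_counting(scores, truth):
    """Mann-Whitney AUC oracle: fraction of concordant positive-negative
    pixel pairs, ties counted half."""
    scores = np.asarray(scores, float).ravel()
    truth = np.asarray(truth, bool).ravel()
    pos = scores[truth]
    neg = scores[~truth]
    diff = pos[:, None] - neg[None, :]
    return (np.sum(diff > 0) + 0.5 * np.sum(diff == 0)) / (len(pos) * len(neg))
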
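"""Shared simulation helpers for the test suite."""

import numpy as np
import pytest


def trivariate_correlations(rho_xy, rho_zy, rho_zx, n, reps, rng, rank=False):
    """Sample correlations (r_xy, r_zy, r_zx) from `reps` trivariate-normal
    datasets of size n with the given population correlations.

    With ``rank=True`` the correlations are Spearman (computed on ranks).
    Returns three arrays of shape (reps,).
    """
    C = np.array(
        [[1.0, rho_xy, rho_zx], [rho_xy, 1.0, rho_zy], [rho_zx, rho_zy, 1.0]]
    )
    L = np.linalg.cholesky(C)
    X = rng.standard_normal((reps, n, 3)) @ L.T
    if rank:
        X = X.argsort(axis=1).argsort(axis=1).astype(float)
    Xc = X - X.mean(axis=1, keepdims=True)
    Xc /= np.sqrt((Xc**2).sum(axis=1, keepdims=True))
    r_xy = (Xc[:, :, 0] * Xc[:, :, 1]).sum(axis=1)
    r_zy = (Xc[:, :, 2] * Xc[:, :, 1]).sum(axis=1)
    r_zx = (Xc[:, :, 2] * Xc[:, :, 0]).sum(axis=1)
    return r_xy, r_zy, r_zx


def random_valid_triples(reps, rng, r_max=0.9):
    """Random correlation triples drawn from actual trivariate-normal
    correlation matrices (so each triple is jointly feasible)."""
    out = np.empty((reps, 3))
    k = 0
    while k < reps:
        a = rng.uniform(-r_max, r_max, size=3)
        C = np.array([[1, a[0], a[2]], [a[0], 1, a[1]], [a[2], a[1], 1]])
        if np.linalg.eigvalsh(C)[0] > 1e-3:
            out[k] = a
            k += 1
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
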
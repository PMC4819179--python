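"""Shared fixtures and brute-force index-loop oracles.

The oracles deliberately expand every tensor to all 81 (or 9) Cartesian
components and sum with explicit Python loops, independent of the
vectorized implementations they check.
"""

import itertools

import numpy as np
import pytest

from kfakit.tensors import DiffusionTensor, KurtosisTensor, W_INDICES


@pytest.fixture
def rng():
    return np.random.default_rng(20160404)


def random_diffusion(rng, positive=True) -> DiffusionTensor:
    """Random diffusion tensor; positive-definite by default, um^2/ms scale."""
    a = rng.standard_normal((3, 3))
    m = a @ a.T / 3.0 if positive else (a + a.T) / 2.0
    return DiffusionTensor.from_matrix(m)


def random_kurtosis(rng, scale=1.0) -> KurtosisTensor:
    return KurtosisTensor(scale * rng.standard_normal(15))


# ---------------------------------------------------------------------------
# index-loop oracles
# ---------------------------------------------------------------------------

def loop_quadratic(dmat, n):
    """n_i n_j D_ij by explicit 9-term loop."""
    total = 0.0
    for i in range(3):
        for j in range(3):
            total += n[i] * n[j] * dmat[i, j]
    return total


def loop_quartic(wfull, n):
    """n_i n_j n_k n_l W_ijkl by explicit 81-term loop."""
    total = 0.0
    for i, j, k, l in itertools.product(range(3), repeat=4):
        total += n[i] * n[j] * n[k] * n[l] * wfull[i, j, k, l]
    return total


def loop_frobenius_sq(wfull):
    """Sum of squares over all 81 Cartesian components."""
    total = 0.0
    for idx in itertools.product(range(3), repeat=4):
        total += wfull[idx] ** 2
    return total


def loop_iso_rank4():
    """I4_ijkl = (d_ij d_kl + d_ik d_jl + d_il d_jk) / 3, explicit."""
    d = np.eye(3)
    out = np.zeros((3, 3, 3, 3))
    for i, j, k, l in itertools.product(range(3), repeat=4):
        out[i, j, k, l] = (d[i, j] * d[k, l] + d[i, k] * d[j, l]
                           + d[i, l] * d[j, k]) / 3.0
    return out


def loop_wbar(wfull):
    """Spherical mean of W(n) via the identity <W, I4>/5 computed by loop."""
    total = 0.0
    for i in range(3):
        for j in range(3):
            total += wfull[i, i, j, j]
    return total / 5.0


def loop_kfa(wfull):
    wb = loop_wbar(wfull)
    dev = wfull - wb * loop_iso_rank4()
    den = loop_frobenius_sq(wfull)
    if den == 0:
        return 0.0
    return np.sqrt(loop_frobenius_sq(dev) / den)


def loop_predict_signal(s0, dmat, wfull, bvals, bvecs):
    """Exponentiated cumulant expansion, one measurement at a time."""
    md = np.trace(dmat) / 3.0
    out = []
    for b, n in zip(bvals, bvecs):
        expo = -b * loop_quadratic(dmat, n) \
            + b ** 2 / 6.0 * md ** 2 * loop_quartic(wfull, n)
        out.append(s0 * np.exp(expo))
    return np.array(out)


def assert_full_symmetric(wfull, atol=0.0):
    for perm in itertools.permutations(range(4)):
        np.testing.assert_allclose(wfull, np.transpose(wfull, perm),
                                   atol=atol)


__all__ = ["random_diffusion", "random_kurtosis", "loop_quadratic",
           "loop_quartic", "loop_frobenius_sq", "loop_iso_rank4",
           "loop_wbar", "loop_kfa", "loop_predict_signal",
           "assert_full_symmetric", "W_INDICES"]
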
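"""Fast two-shell directional kurtosis and the KFA proxy.

From signals on two shells sharing the same direction set, the apparent
diffusivity and kurtosis along each direction follow in closed form by
inverting the DKI log-signal expansion on that direction:

    y_s = ln(S_s / S0),  s = 1, 2
    D(n) = (b1^2 y2 - b2^2 y1) / (b1 b2 (b2 - b1))
    K(n) = 6 (b1 y2 - b2 y1) / (D(n)^2 b1 b2 (b2 - b1))

No tensor fit is involved.  The KFA proxy is then the normalized directional
dispersion std(K)/rms(K) over the sampled directions — the same std/rms form
as FA, but applied to per-direction apparent kurtosis values.  It tracks the
true (tensor-derived) KFA without requiring the 22-parameter DKI fit; its
numeric range is not calibrated to KFA's and no calibration mapping exists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import (
    InsufficientDataError,
    InvalidInputError,
    InvalidSchemeError,
)
from .model import AcquisitionScheme

__all__ = ["TwoShellScheme", "DirectionalKurtosis", "two_shell_dk",
           "kfa_proxy", "proxy_map"]


@dataclass(frozen=True)
class TwoShellScheme:
    """Two-shell acquisition: shells b1 < b2 sharing one direction set."""

    b1: float
    b2: float
    directions: np.ndarray

    def __post_init__(self):
        if not (np.isfinite(self.b1) and np.isfinite(self.b2)):
            raise InvalidSchemeError("non-finite b-values")
        if self.b1 == self.b2:
            raise InvalidSchemeError("b1 = b2 is not a valid combination")
        if not 0 < self.b1 < self.b2:
            raise InvalidSchemeError(
                f"need 0 < b1 < b2, got b1={self.b1}, b2={self.b2}")
        d = np.asarray(self.directions, dtype=float)
        if d.ndim != 2 or d.shape[1] != 3 or d.shape[0] < 3:
            raise InvalidSchemeError("need >= 3 unit directions, shape (N, 3)")
        norms = np.linalg.norm(d, axis=1)
        if np.any(np.abs(norms - 1) > 1e-6):
            raise InvalidSchemeError("directions must be unit-norm")
        object.__setattr__(self, "directions", d)

    @property
    def n_directions(self) -> int:
        return self.directions.shape[0]

    def to_acquisition(self) -> AcquisitionScheme:
        """Measurement order: one b = 0, then shell 1, then shell 2."""
        n = self.n_directions
        bvals = np.concatenate([[0.0], np.full(n, self.b1),
                                np.full(n, self.b2)])
        bvecs = np.vstack([np.zeros(3), self.directions, self.directions])
        return AcquisitionScheme(bvals, bvecs)


@dataclass(frozen=True)
class DirectionalKurtosis:
    """Per-direction apparent (D, K) with a validity mask."""

    d: np.ndarray
    k: np.ndarray
    valid: np.ndarray


def two_shell_dk(s0, s1, s2, b1: float, b2: float, eps: float = 1e-12):
    """Closed-form per-direction (D, K) from two shells.

    Accepts scalars or aligned arrays.  Returns ``(D, K, valid)``; entries
    with non-positive signals or apparent diffusivity <= ``eps`` are marked
    invalid (K set to nan) rather than raising.
    """
    if b1 == b2:
        raise InvalidSchemeError("b1 = b2 is not a valid combination")
    if not 0 < b1 < b2:
        raise InvalidSchemeError(f"need 0 < b1 < b2, got ({b1}, {b2})")
    s0 = np.asarray(s0, dtype=float)
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    pos = (s0 > 0) & (s1 > 0) & (s2 > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        y1 = np.log(np.where(pos, s1 / s0, np.nan))
        y2 = np.log(np.where(pos, s2 / s0, np.nan))
        denom = b1 * b2 * (b2 - b1)
        d = (b1 ** 2 * y2 - b2 ** 2 * y1) / denom
        k = 6.0 * (b1 * y2 - b2 * y1) / (d ** 2 * denom)
    valid = pos & np.isfinite(d) & (d > eps) & np.isfinite(k)
    k = np.where(valid, k, np.nan)
    d = np.where(pos, d, np.nan)
    if d.ndim == 0:
        return float(d), float(k), bool(valid)
    return d, k, valid


#: dimensionless kurtosis magnitude below which K is treated as exactly
#: zero (roundoff of the log-signal inversion), so Gaussian voxels map to
#: proxy = 0 instead of std/rms of floating-point noise
_K_ROUNDOFF = 1e-10


def kfa_proxy(k: np.ndarray, valid: np.ndarray | None = None,
              min_directions: int = 3) -> float:
    """std(K)/rms(K) over valid directions (population normalization).

    Always <= 1 (std <= rms by construction); 0 when all K are equal or
    rms vanishes.  Raises :class:`InsufficientDataError` below
    ``min_directions`` valid entries.
    """
    k = np.asarray(k, dtype=float).ravel()
    if valid is None:
        valid = np.isfinite(k)
    else:
        valid = np.asarray(valid, bool).ravel() & np.isfinite(k)
    kv = k[valid]
    if kv.size < max(min_directions, 3):
        raise InsufficientDataError(
            f"{kv.size} valid directions < required {max(min_directions, 3)}")
    rms = np.sqrt(np.mean(kv ** 2))
    if rms <= _K_ROUNDOFF:  # kurtosis indistinguishable from zero
        return 0.0
    return float(np.std(kv) / rms)


def _proxy_from_signals(s0, s1, s2, b1, b2, min_directions=3, eps=1e-12):
    """Vectorized proxy over leading voxel axes; returns (proxy, valid)."""
    _, k, valid = two_shell_dk(s0[..., None] if np.ndim(s0) < np.ndim(s1)
                               else s0, s1, s2, b1, b2, eps)
    n_valid = valid.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        k0 = np.where(valid, k, 0.0)
        mean = k0.sum(axis=-1) / n_valid
        msq = (k0 ** 2).sum(axis=-1) / n_valid
        var = msq - mean ** 2
        proxy = np.sqrt(np.clip(var, 0.0, None) / msq)
    ok = (n_valid >= max(min_directions, 3)) & (msq > _K_ROUNDOFF ** 2)
    proxy = np.where(ok, proxy, np.where(n_valid >= max(min_directions, 3),
                                         0.0, np.nan))
    voxel_valid = n_valid >= max(min_directions, 3)
    return proxy, voxel_valid


def proxy_map(volume: np.ndarray, scheme: TwoShellScheme,
              min_directions: int = 3, mask: np.ndarray | None = None,
              eps: float = 1e-12):
    """Voxel-wise KFA proxy over a volume.

    ``volume`` has shape (..., 1 + 2N) aligned with
    ``scheme.to_acquisition()`` order (b=0 image, shell 1, shell 2).  Returns
    ``(proxy, valid)`` arrays of the leading shape; voxels outside ``mask``
    or with fewer than ``min_directions`` valid directions get nan/False.
    """
    vol = np.asarray(volume, dtype=float)
    n = scheme.n_directions
    if vol.shape[-1] != 1 + 2 * n:
        raise InvalidInputError(
            f"last axis {vol.shape[-1]} != 1 + 2*{n} expected for the scheme")
    s0 = vol[..., 0]
    s1 = vol[..., 1:1 + n]
    s2 = vol[..., 1 + n:]
    proxy, valid = _proxy_from_signals(s0, s1, s2, scheme.b1, scheme.b2,
                                       min_directions, eps)
    if mask is not None:
        mask = np.asarray(mask, bool)
        proxy = np.where(mask, proxy, np.nan)
        valid = valid & mask
    return proxy, valid
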
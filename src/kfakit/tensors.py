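"""Diffusion and kurtosis tensor containers and their scalar invariants.

The diffusion tensor ``D`` is a symmetric 3x3 tensor (units um^2/ms) stored
as its six unique components.  The kurtosis tensor ``W`` is a fully symmetric
rank-4 tensor (dimensionless) stored as its fifteen unique components in the
sorted multi-index order

    xxxx, yyyy, zzzz, xxxy, xxxz, xyyy, yyyz, xzzz, yzzz,
    xxyy, xxzz, yyzz, xxyz, xyyz, xyzz

with Cartesian multiplicities (1, 4 or 6 or 12) accounting for the index
permutations each unique component represents.  All norms here are tensor
Frobenius norms, i.e. sums of squares over all 81 Cartesian components,
which makes every derived scalar rotation invariant.

Scalar metrics
--------------
MD   mean diffusivity, trace(D)/3.
FA   fractional anisotropy: sqrt(3/2) * ||lambda - MD|| / ||lambda||,
     the normalized dispersion of D's eigenvalues, in [0, 1].
Wbar spherical mean of the quartic form W(n) = n_i n_j n_k n_l W_ijkl.
MK   mean kurtosis: average of the apparent kurtosis K(n) over a dense
     uniform direction set.
KFA  kurtosis fractional anisotropy: ||W - Wbar*I4||_F / ||W||_F where I4 is
     the fully symmetric isotropic rank-4 tensor, in [0, 1].  KFA isolates
     the anisotropy of W alone and survives fiber geometries (orthogonal
     crossings) in which FA collapses.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .exceptions import DegenerateDirectionError, InvalidInputError

__all__ = [
    "DiffusionTensor",
    "KurtosisTensor",
    "ScalarMetrics",
    "W_INDICES",
    "W_MULTIPLICITY",
    "ISO_RANK4_15",
    "md_fa",
    "wbar",
    "kfa",
    "apparent_dk",
    "mean_kurtosis",
    "quartic_design",
    "quadratic_design",
    "frobenius_sq",
    "rotate_diffusion",
    "rotate_kurtosis",
    "random_rotation",
    "fa_from_eigenvalues",
    "md_fa_from_dt6",
    "wbar_from_w15",
    "kfa_from_w15",
]

# Unique component multi-indices of a fully symmetric rank-4 tensor over
# {x=0, y=1, z=2}, in the documented storage order.
W_INDICES: tuple[tuple[int, int, int, int], ...] = (
    (0, 0, 0, 0), (1, 1, 1, 1), (2, 2, 2, 2),
    (0, 0, 0, 1), (0, 0, 0, 2), (0, 1, 1, 1), (1, 1, 1, 2),
    (0, 2, 2, 2), (1, 2, 2, 2),
    (0, 0, 1, 1), (0, 0, 2, 2), (1, 1, 2, 2),
    (0, 0, 1, 2), (0, 1, 1, 2), (0, 1, 2, 2),
)

#: number of distinct Cartesian index permutations per unique component
W_MULTIPLICITY = np.array([1, 1, 1, 4, 4, 4, 4, 4, 4, 6, 6, 6, 12, 12, 12],
                          dtype=float)

#: isotropic rank-4 tensor I4_ijkl = (d_ij d_kl + d_ik d_jl + d_il d_jk)/3
#: in 15-component storage; its quartic form is 1 for every unit vector.
ISO_RANK4_15 = np.array(
    [1.0, 1.0, 1.0, 0, 0, 0, 0, 0, 0, 1 / 3, 1 / 3, 1 / 3, 0, 0, 0])

_DT_INDICES = ((0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2))


def _check_finite(arr: np.ndarray, what: str) -> np.ndarray:
    arr = np.asarray(arr, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError(f"{what} contains non-finite values")
    return arr


@dataclass(frozen=True)
class DiffusionTensor:
    """Symmetric rank-2 diffusion tensor, um^2/ms.

    Stored as the six unique components (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz).
    Fits may produce negative eigenvalues; those are flagged downstream,
    never rejected here.
    """

    components: np.ndarray = field()

    def __post_init__(self):
        comp = _check_finite(self.components, "diffusion tensor")
        if comp.shape != (6,):
            raise InvalidInputError(
                f"expected 6 unique components, got shape {comp.shape}")
        object.__setattr__(self, "components", comp)

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "DiffusionTensor":
        m = _check_finite(m, "diffusion tensor matrix")
        if m.shape != (3, 3) or not np.allclose(m, m.T, atol=1e-10):
            raise InvalidInputError("expected a symmetric 3x3 matrix")
        return cls(np.array([m[i, j] for i, j in _DT_INDICES]))

    @classmethod
    def diagonal(cls, dx: float, dy: float, dz: float) -> "DiffusionTensor":
        return cls(np.array([dx, dy, dz, 0.0, 0.0, 0.0]))

    @classmethod
    def isotropic(cls, d: float) -> "DiffusionTensor":
        return cls.diagonal(d, d, d)

    @property
    def matrix(self) -> np.ndarray:
        c = self.components
        return np.array([[c[0], c[3], c[4]],
                         [c[3], c[1], c[5]],
                         [c[4], c[5], c[2]]])

    @property
    def eigenvalues(self) -> np.ndarray:
        """Eigenvalues sorted descending (lambda1 >= lambda2 >= lambda3)."""
        return np.linalg.eigvalsh(self.matrix)[::-1]

    @property
    def md(self) -> float:
        return float(self.components[:3].sum() / 3.0)

    def along(self, n: np.ndarray) -> float:
        """Apparent diffusivity D(n) = n_i n_j D_ij for a unit vector n."""
        n = np.asarray(n, dtype=float)
        return float(n @ self.matrix @ n)


@dataclass(frozen=True)
class KurtosisTensor:
    """Fully symmetric rank-4 kurtosis tensor, dimensionless.

    Stored as the fifteen unique components in :data:`W_INDICES` order.
    """

    components: np.ndarray = field()

    def __post_init__(self):
        comp = _check_finite(self.components, "kurtosis tensor")
        if comp.shape != (15,):
            raise InvalidInputError(
                f"expected 15 unique components, got shape {comp.shape}")
        object.__setattr__(self, "components", comp)

    @classmethod
    def zeros(cls) -> "KurtosisTensor":
        return cls(np.zeros(15))

    @classmethod
    def isotropic(cls, scale: float = 1.0) -> "KurtosisTensor":
        return cls(scale * ISO_RANK4_15)

    @classmethod
    def from_full(cls, full: np.ndarray, symmetrize: bool = False
                  ) -> "KurtosisTensor":
        full = _check_finite(full, "rank-4 tensor")
        if full.shape != (3, 3, 3, 3):
            raise InvalidInputError("expected a 3x3x3x3 array")
        if symmetrize:
            full = full_symmetrize(full)
        return cls(np.array([full[idx] for idx in W_INDICES]))

    @property
    def full(self) -> np.ndarray:
        """All 81 Cartesian components (fully symmetric expansion)."""
        out = np.zeros((3, 3, 3, 3))
        for value, idx in zip(self.components, W_INDICES):
            for perm in set(itertools.permutations(idx)):
                out[perm] = value
        return out

    def quartic_form(self, n: np.ndarray) -> float:
        """W(n) = n_i n_j n_k n_l W_ijkl for a unit vector n."""
        n = np.asarray(n, dtype=float)
        return float(quartic_design(n) @ self.components)


@dataclass(frozen=True)
class ScalarMetrics:
    """Bundle of the per-voxel scalar metrics."""

    md: float      # um^2/ms
    fa: float      # dimensionless, [0, 1]
    wbar: float    # dimensionless
    mk: float      # dimensionless
    kfa: float     # dimensionless, [0, 1]


# ---------------------------------------------------------------------------
# vectorized building blocks (array-first; the object API wraps these)
# ---------------------------------------------------------------------------

def quadratic_design(dirs: np.ndarray) -> np.ndarray:
    """Rows of n_i n_j monomials matching 6-component D storage.

    ``quadratic_design(dirs) @ dt6`` equals D(n) per direction (off-diagonal
    components carry multiplicity 2).
    """
    d = np.asarray(dirs, dtype=float)
    x, y, z = d[..., 0], d[..., 1], d[..., 2]
    return np.stack([x * x, y * y, z * z,
                     2 * x * y, 2 * x * z, 2 * y * z], axis=-1)


def quartic_design(dirs: np.ndarray) -> np.ndarray:
    """Rows of multiplicity-weighted quartic monomials in W storage order.

    ``quartic_design(dirs) @ w15`` equals W(n) per direction.
    """
    d = np.asarray(dirs, dtype=float)
    x, y, z = d[..., 0], d[..., 1], d[..., 2]
    return np.stack([
        x ** 4, y ** 4, z ** 4,
        4 * x ** 3 * y, 4 * x ** 3 * z, 4 * x * y ** 3, 4 * y ** 3 * z,
        4 * x * z ** 3, 4 * y * z ** 3,
        6 * x ** 2 * y ** 2, 6 * x ** 2 * z ** 2, 6 * y ** 2 * z ** 2,
        12 * x ** 2 * y * z, 12 * x * y ** 2 * z, 12 * x * y * z ** 2,
    ], axis=-1)


def frobenius_sq(w15: np.ndarray) -> np.ndarray:
    """Squared Frobenius norm (81-component sum) from 15-component storage."""
    w15 = np.asarray(w15, dtype=float)
    return np.einsum("...i,i,...i->...", w15, W_MULTIPLICITY, w15)


def fa_from_eigenvalues(eigs: np.ndarray) -> np.ndarray:
    """FA = sqrt(3/2) * std(lambda) / rms(lambda), population-normalized."""
    eigs = np.asarray(eigs, dtype=float)
    mean = eigs.mean(axis=-1, keepdims=True)
    num = ((eigs - mean) ** 2).sum(axis=-1)
    den = (eigs ** 2).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * num / den)
    fa = np.where(den > 0, fa, 0.0)
    return np.clip(fa, 0.0, 1.0)


def md_fa_from_dt6(dt6: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (MD, FA) from arrays of 6-component diffusion tensors."""
    dt6 = np.asarray(dt6, dtype=float)
    c = dt6
    mats = np.stack([
        np.stack([c[..., 0], c[..., 3], c[..., 4]], axis=-1),
        np.stack([c[..., 3], c[..., 1], c[..., 5]], axis=-1),
        np.stack([c[..., 4], c[..., 5], c[..., 2]], axis=-1),
    ], axis=-2)
    eigs = np.linalg.eigvalsh(mats)
    md = dt6[..., :3].sum(axis=-1) / 3.0
    return md, fa_from_eigenvalues(eigs)


def wbar_from_w15(w15: np.ndarray) -> np.ndarray:
    """Spherical mean of W(n): (Wxxxx+Wyyyy+Wzzzz+2(Wxxyy+Wxxzz+Wyyzz))/5."""
    w15 = np.asarray(w15, dtype=float)
    return (w15[..., 0] + w15[..., 1] + w15[..., 2]
            + 2.0 * (w15[..., 9] + w15[..., 10] + w15[..., 11])) / 5.0


def kfa_from_w15(w15: np.ndarray) -> np.ndarray:
    """Vectorized KFA; returns 0 where ||W|| = 0."""
    w15 = np.asarray(w15, dtype=float)
    wb = wbar_from_w15(w15)
    dev = w15 - wb[..., None] * ISO_RANK4_15
    num = frobenius_sq(dev)
    den = frobenius_sq(w15)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.sqrt(num / den)
    out = np.where(den > 0, out, 0.0)
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# scalar-metric operations (object API)
# ---------------------------------------------------------------------------

def md_fa(d: DiffusionTensor) -> tuple[float, float]:
    """Mean diffusivity and fractional anisotropy of ``d``.

    FA is the eigenvalue dispersion sqrt(3/2)*||lambda - MD||/||lambda||;
    it is 0 for isotropic tensors and 1 in the stick limit diag(d, 0, 0).
    The all-zero tensor returns FA = 0 by convention.
    """
    eigs = d.eigenvalues
    md = float(eigs.mean())
    return md, float(fa_from_eigenvalues(eigs))


def wbar(w: KurtosisTensor) -> float:
    """Mean of the kurtosis tensor: the spherical average of W(n)."""
    return float(wbar_from_w15(w.components))


def kfa(w: KurtosisTensor) -> float:
    """Kurtosis fractional anisotropy ||W - Wbar*I4||_F / ||W||_F.

    Wbar*I4 is the orthogonal projection of W onto the isotropic rank-4
    tensor, so KFA is guaranteed in [0, 1]; a vanishing W returns 0.
    """
    return float(kfa_from_w15(w.components))


def apparent_dk(d: DiffusionTensor, w: KurtosisTensor, n: np.ndarray,
                eps: float = 1e-12) -> tuple[float, float]:
    """Apparent diffusivity D(n) and apparent kurtosis K(n) along ``n``.

    K(n) = (MD^2 / D(n)^2) * n_i n_j n_k n_l W_ijkl.  Raises
    :class:`DegenerateDirectionError` when D(n) <= ``eps``.
    """
    n = _check_finite(n, "direction")
    norm = np.linalg.norm(n)
    if abs(norm - 1.0) > 1e-8:
        raise InvalidInputError(f"direction is not unit length (|n|={norm})")
    dn = d.along(n)
    if dn <= eps:
        raise DegenerateDirectionError(
            f"apparent diffusivity {dn} <= eps={eps} along {n}")
    wn = w.quartic_form(n)
    md = d.md
    return float(dn), float(md * md / (dn * dn) * wn)


def mean_kurtosis(d: DiffusionTensor, w: KurtosisTensor,
                  directions: np.ndarray | None = None) -> float:
    """Mean kurtosis: average of K(n) over a dense uniform direction set.

    Defaults to the packaged 1000-point spherical quadrature set; requires
    >= 60 approximately uniform directions (quadrature error <~1e-3 on
    tissue-scale tensors; <3e-4 with the default set).
    """
    if directions is None:
        from .directions import quadrature_set
        directions = quadrature_set()
    directions = np.asarray(directions, dtype=float)
    if directions.ndim != 2 or directions.shape[0] < 60:
        raise InvalidInputError(
            "mean kurtosis needs >= 60 approximately uniform directions")
    dn = quadratic_design(directions) @ d.components
    if np.any(dn <= 1e-12):
        raise DegenerateDirectionError(
            "apparent diffusivity vanished on the quadrature set")
    wn = quartic_design(directions) @ w.components
    md = d.md
    return float(np.mean(md * md / dn ** 2 * wn))


# ---------------------------------------------------------------------------
# rotations
# ---------------------------------------------------------------------------

def full_symmetrize(t: np.ndarray) -> np.ndarray:
    """Average a rank-4 tensor over all 24 index permutations."""
    out = np.zeros_like(t)
    perms = list(itertools.permutations(range(4)))
    for perm in perms:
        out += np.transpose(t, perm)
    return out / len(perms)


def rotate_diffusion(d: DiffusionTensor, rot: np.ndarray) -> DiffusionTensor:
    """R D R^T."""
    return DiffusionTensor.from_matrix(rot @ d.matrix @ rot.T)


def rotate_kurtosis(w: KurtosisTensor, rot: np.ndarray) -> KurtosisTensor:
    """W'_ijkl = R_ia R_jb R_kc R_ld W_abcd."""
    full = np.einsum("ia,jb,kc,ld,abcd->ijkl", rot, rot, rot, rot, w.full)
    return KurtosisTensor.from_full(full)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-uniform rotation matrix via QR of a Gaussian matrix."""
    m = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(m)
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
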
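"""Synthetic diffusion-weighted signals with exact ground-truth tensors.

Voxels are mixtures of axially symmetric Gaussian compartments.  For such a
mixture the cumulant tensors of the DKI expansion are exact and closed-form:

    D      = sum_c f_c D_c
    W_ijkl = (3 / MD^2) * FullSym[ sum_c f_c D_c_ij D_c_kl - D_ij D_kl ]

so every simulated voxel carries an analytically exact (D, W) pair, which is
what makes oracle testing of estimators possible.  The module also provides
the fiber-mixing experiment (signals from three orthogonal bundles combined
with weights (1-2a, a, a)), brain-like voxel populations stratified by FA
band, a 3x3 orthogonal-bundle phantom, and seeded Rician noise.

Units: diffusivities in um^2/ms, b-values in ms/um^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError, InvalidParameterError
from .model import AcquisitionScheme, predict_signal_many
from .tensors import (
    DiffusionTensor,
    KurtosisTensor,
    full_symmetrize,
    kfa_from_w15,
    md_fa_from_dt6,
)

__all__ = [
    "FiberCompartment", "VoxelModel", "VolumeFractionTensor", "NoiseSpec",
    "compartment_tensor", "mixture_cumulants", "gaussian_mixture_signal",
    "mix_signals", "volume_fraction_index", "add_rician_noise",
    "synthetic_population", "Population", "orthogonal_phantom", "Phantom",
    "default_fiber_kernel", "FREE_WATER_DIFFUSIVITY",
]

#: room-temperature free water diffusivity used for phantom background
FREE_WATER_DIFFUSIVITY = 2.2

# default single-fiber kernel for mixing sweeps: WM-like fiber plus a 30%
# isotropic compartment (gives single-fiber FA ~= 0.59, KFA ~= 0.9)
DEFAULT_KERNEL = dict(d_parallel=2.0, d_perpendicular=0.4,
                      iso_fraction=0.3, d_iso=1.0)


@dataclass(frozen=True)
class FiberCompartment:
    """Axially symmetric Gaussian compartment."""

    orientation: np.ndarray
    d_parallel: float
    d_perpendicular: float
    fraction: float

    def __post_init__(self):
        u = np.asarray(self.orientation, dtype=float)
        norm = np.linalg.norm(u)
        if not np.isfinite(norm) or norm < 1e-12:
            raise InvalidInputError("compartment orientation must be nonzero")
        object.__setattr__(self, "orientation", u / norm)
        if not (self.d_parallel >= self.d_perpendicular >= 0):
            raise InvalidInputError(
                "need d_parallel >= d_perpendicular >= 0, got "
                f"({self.d_parallel}, {self.d_perpendicular})")
        if not 0 <= self.fraction <= 1:
            raise InvalidInputError(f"fraction {self.fraction} outside [0,1]")

    @classmethod
    def isotropic(cls, d: float, fraction: float) -> "FiberCompartment":
        return cls(np.array([0.0, 0.0, 1.0]), d, d, fraction)


def compartment_tensor(c: FiberCompartment) -> DiffusionTensor:
    """D = d_perp*I + (d_par - d_perp) * u u^T."""
    u = c.orientation
    m = c.d_perpendicular * np.eye(3) \
        + (c.d_parallel - c.d_perpendicular) * np.outer(u, u)
    return DiffusionTensor.from_matrix(m)


@dataclass(frozen=True)
class VoxelModel:
    """Mixture of Gaussian compartments with fractions summing to one."""

    compartments: tuple

    def __post_init__(self):
        comps = tuple(self.compartments)
        if not comps:
            raise InvalidInputError("voxel needs at least one compartment")
        total = sum(c.fraction for c in comps)
        if abs(total - 1.0) > 1e-9:
            raise InvalidInputError(f"fractions sum to {total}, expected 1")
        object.__setattr__(self, "compartments", comps)


def mixture_cumulants(voxel: VoxelModel
                      ) -> tuple[DiffusionTensor, KurtosisTensor]:
    """Exact (D, W) of a Gaussian mixture.

    Satisfies the per-direction identity
    K(n) = 3 (sum_c f_c D_c(n)^2 - D(n)^2) / D(n)^2.
    """
    mats = [compartment_tensor(c).matrix for c in voxel.compartments]
    fracs = [c.fraction for c in voxel.compartments]
    d = sum(f * m for f, m in zip(fracs, mats))
    second = sum(f * np.einsum("ij,kl->ijkl", m, m)
                 for f, m in zip(fracs, mats))
    cov = second - np.einsum("ij,kl->ijkl", d, d)
    md = np.trace(d) / 3.0
    dt = DiffusionTensor.from_matrix(d)
    if md == 0:
        return dt, KurtosisTensor.zeros()
    w = KurtosisTensor.from_full(3.0 / md ** 2 * full_symmetrize(cov))
    return dt, w


def gaussian_mixture_signal(voxel: VoxelModel, scheme: AcquisitionScheme,
                            s0: float = 1.0) -> np.ndarray:
    """Exact multi-Gaussian signal sum_c f_c exp(-b n D_c n).

    Unlike :func:`~kfakit.model.predict_signal` on the mixture cumulants,
    this carries all cumulant orders, so the two agree only to O(b^3).
    """
    b = scheme.bvals
    n = scheme.bvecs
    out = np.zeros(len(scheme))
    for c in voxel.compartments:
        dn = np.einsum("mi,ij,mj->m", n, compartment_tensor(c).matrix, n)
        out += c.fraction * np.exp(-b * dn)
    return s0 * out


# ---------------------------------------------------------------------------
# fiber mixing experiment
# ---------------------------------------------------------------------------

#: default mixing grid, 0 .. 1/3 in steps of 0.03
DEFAULT_ALPHAS = np.append(np.arange(0.0, 1.0 / 3.0, 0.03), 1.0 / 3.0)


def mix_signals(sx: np.ndarray, sy: np.ndarray, sz: np.ndarray,
                alpha: float) -> np.ndarray:
    """S(a) = (1 - 2a) Sx + a Sy + a Sz, for a in [0, 1/3].

    a = 0 is the pure x-bundle signal; a = 1/3 mixes the three orthogonal
    bundles in equal amounts.
    """
    if not 0.0 <= alpha <= 1.0 / 3.0 + 1e-12:
        raise InvalidParameterError(f"alpha {alpha} outside [0, 1/3]")
    sx, sy, sz = (np.asarray(s, dtype=float) for s in (sx, sy, sz))
    if not sx.shape == sy.shape == sz.shape:
        raise InvalidInputError("signal blocks must share one scheme")
    return (1.0 - 2.0 * alpha) * sx + alpha * sy + alpha * sz


@dataclass(frozen=True)
class VolumeFractionTensor:
    """Diagonal tensor of fiber volume fractions along x, y, z."""

    fractions: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.fractions, dtype=float)
        if v.shape != (3,) or np.any(v < 0):
            raise InvalidInputError("need 3 non-negative volume fractions")
        if abs(v.sum() - 1.0) > 1e-9:
            raise InvalidInputError(f"fractions sum to {v.sum()}, expected 1")
        object.__setattr__(self, "fractions", v)


def volume_fraction_index(v: VolumeFractionTensor | np.ndarray) -> float:
    """FA-analogue of the volume-fraction tensor: 1 for a single direction,
    0 for equal thirds."""
    vv = v.fractions if isinstance(v, VolumeFractionTensor) else \
        np.asarray(v, dtype=float)
    if np.all(vv == 0):
        raise InvalidInputError("all-zero volume fractions")
    mean = vv.mean()
    vi = np.sqrt(1.5 * ((vv - mean) ** 2).sum() / (vv ** 2).sum())
    return float(np.clip(vi, 0.0, 1.0))


# ---------------------------------------------------------------------------
# noise
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseSpec:
    """Rician noise level: SNR defined at b = 0, plus realization count."""

    snr: float
    n_realizations: int = 1
    seed: int = 0

    def __post_init__(self):
        if not (self.snr > 0):
            raise InvalidInputError("SNR must be positive (or inf)")
        if self.n_realizations < 1:
            raise InvalidInputError("need n_realizations >= 1")


def noise_rng(seed: int, realization: int = 0) -> np.random.Generator:
    """Generator for one realization; any single realization is reproducible
    in isolation from (seed, realization)."""
    return np.random.default_rng(np.random.SeedSequence(
        entropy=int(seed), spawn_key=(int(realization),)))


def add_rician_noise(signals: np.ndarray, spec: NoiseSpec,
                     s0_ref: float = 1.0, realization: int = 0,
                     rng: np.random.Generator | None = None) -> np.ndarray:
    """One Rician noise realization: S -> sqrt((S + s g1)^2 + (s g2)^2).

    ``s = s0_ref / SNR`` with g1, g2 independent standard normals, i.e. the
    magnitude of a complex signal with additive Gaussian noise per channel.
    Infinite SNR returns the input unchanged.
    """
    signals = np.asarray(signals, dtype=float)
    if np.isinf(spec.snr):
        return signals.copy()
    sigma = s0_ref / spec.snr
    if rng is None:
        rng = noise_rng(spec.seed, realization)
    g1 = rng.standard_normal(signals.shape)
    g2 = rng.standard_normal(signals.shape)
    return np.sqrt((signals + sigma * g1) ** 2 + (sigma * g2) ** 2)


# ---------------------------------------------------------------------------
# brain-like voxel populations
# ---------------------------------------------------------------------------

def _random_unit(rng) -> np.ndarray:
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


def _fiber_bundle(rng, u, f) -> list:
    """WM-like fiber bundle: restricted intra-neurite stick plus an
    anisotropic hindered extracellular compartment sharing the axis.

    The large perpendicular diffusivity contrast between the two is what
    produces WM-strength kurtosis (Wbar ~ 0.5-1) with high KFA.
    """
    f_intra = rng.uniform(0.35, 0.6)
    return [
        FiberCompartment(u, rng.uniform(1.8, 2.3), rng.uniform(0.02, 0.15),
                         f * f_intra),
        FiberCompartment(u, rng.uniform(1.4, 2.0), rng.uniform(0.5, 0.9),
                         f * (1.0 - f_intra)),
    ]


#: angular spread of GM neurite orientations about the voxel's main axis
_GM_NEURITE_SPREAD = 0.5


def _draw_voxel(rng, kind: str) -> VoxelModel:
    comps = []
    if kind == "wm":
        # one dominant bundle, sometimes a minor crossing bundle
        n_fib = 1 if rng.random() < 0.6 else 2
        iso_f = rng.uniform(0.0, 0.1)
        if n_fib == 1:
            fibs = [1.0 - iso_f]
        else:
            minor = rng.uniform(0.05, 0.25)
            fibs = [(1.0 - iso_f) * (1 - minor), (1.0 - iso_f) * minor]
        for f in fibs:
            comps += _fiber_bundle(rng, _random_unit(rng), f)
        if iso_f > 0:
            comps.append(FiberCompartment.isotropic(
                rng.uniform(0.7, 1.3), iso_f))
    elif kind == "gm":
        # many partially dispersed neurite sticks + two isotropic pools
        # (slow cell-body-like and faster extracellular water) whose
        # diffusivity contrast adds isotropic-variance kurtosis, keeping
        # Wbar realistic while KFA stays low
        n_sticks = rng.integers(8, 16)
        neurite_f = rng.uniform(0.2, 0.4)
        main = _random_unit(rng)
        fracs = rng.dirichlet(np.full(n_sticks, 4.0)) * neurite_f
        for f in fracs:
            u = main + _GM_NEURITE_SPREAD * rng.standard_normal(3)
            u /= np.linalg.norm(u)
            comps.append(FiberCompartment(
                u, rng.uniform(1.5, 2.2), rng.uniform(0.02, 0.3), f))
        rest = 1.0 - neurite_f
        slow_f = rest * rng.uniform(0.3, 0.5)
        comps.append(FiberCompartment.isotropic(rng.uniform(0.4, 0.7),
                                                slow_f))
        comps.append(FiberCompartment.isotropic(rng.uniform(1.0, 1.5),
                                                rest - slow_f))
    elif kind == "crossing":
        # several strong bundles in comparable proportions: low FA, high KFA
        n_fib = rng.integers(2, 4)
        iso_f = rng.uniform(0.0, 0.15)
        fracs = rng.dirichlet(np.full(n_fib, 1.5)) * (1.0 - iso_f)
        for f in fracs:
            comps += _fiber_bundle(rng, _random_unit(rng), f)
        if iso_f > 0:
            comps.append(FiberCompartment.isotropic(
                rng.uniform(0.8, 1.3), iso_f))
    else:  # pragma: no cover
        raise InvalidInputError(f"unknown voxel kind {kind!r}")
    # exact renormalization against float drift
    total = sum(c.fraction for c in comps)
    comps = [FiberCompartment(c.orientation, c.d_parallel,
                              c.d_perpendicular, c.fraction / total)
             for c in comps]
    return VoxelModel(tuple(comps))


@dataclass
class Population:
    """Synthetic voxel population with exact ground-truth tensors."""

    voxels: list
    dt6: np.ndarray
    w15: np.ndarray
    profile: str
    seed: int
    fa: np.ndarray = field(init=False)
    md: np.ndarray = field(init=False)
    kfa: np.ndarray = field(init=False)

    def __post_init__(self):
        self.md, self.fa = md_fa_from_dt6(self.dt6)
        self.kfa = kfa_from_w15(self.w15)

    def __len__(self) -> int:
        return self.dt6.shape[0]

    def __iter__(self):
        for i, v in enumerate(self.voxels):
            yield v, DiffusionTensor(self.dt6[i]), KurtosisTensor(self.w15[i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "voxel": np.arange(len(self)),
            "n_compartments": [len(v.compartments) for v in self.voxels],
            "MD": self.md, "FA": self.fa, "KFA": self.kfa,
        })


def synthetic_population(n_voxels: int, seed: int = 0,
                         profile: str = "mixed") -> Population:
    """Brain-like voxel population with exact (D, W) per voxel.

    Profiles: ``wm_like`` (dominant intra/extra-neurite fiber bundles; FA
    mostly in the 0.6-1 white-matter segmentation band, KFA high),
    ``gm_like`` (dispersed neurite sticks plus isotropic pools; FA mostly
    in 0.1-0.3, KFA low), ``mixed`` (40% WM-like, 40% GM-like, 20% strong
    multi-fiber crossings).  The mixed profile emulates brain-like joint
    FA/KFA/MD marginals under CSF-suppressed acquisition: MD ~ 0.7-1.1
    um^2/ms, Wbar ~ 0.2-1, KFA spanning ~0.1-0.95 with WM-GM contrast.
    Deterministic for fixed (n_voxels, seed, profile).
    """
    if n_voxels < 1:
        raise InvalidInputError("need n_voxels >= 1")
    if profile not in ("wm_like", "gm_like", "mixed"):
        raise InvalidInputError(f"unknown profile {profile!r}")
    rng = np.random.default_rng(seed)
    voxels = []
    for _ in range(n_voxels):
        if profile == "wm_like":
            kind = "wm"
        elif profile == "gm_like":
            kind = "gm"
        else:
            kind = rng.choice(["wm", "gm", "crossing"], p=[0.4, 0.4, 0.2])
        voxels.append(_draw_voxel(rng, kind))
    dt6 = np.empty((n_voxels, 6))
    w15 = np.empty((n_voxels, 15))
    for i, v in enumerate(voxels):
        d, w = mixture_cumulants(v)
        dt6[i] = d.components
        w15[i] = w.components
    return Population(voxels, dt6, w15, profile, seed)


# ---------------------------------------------------------------------------
# orthogonal-bundle phantom
# ---------------------------------------------------------------------------

def default_fiber_kernel(orientation) -> VoxelModel:
    """Single-fiber voxel: WM-like fiber + 30% isotropic compartment."""
    k = DEFAULT_KERNEL
    return VoxelModel((
        FiberCompartment(np.asarray(orientation, float), k["d_parallel"],
                         k["d_perpendicular"], 1.0 - k["iso_fraction"]),
        FiberCompartment.isotropic(k["d_iso"], k["iso_fraction"]),
    ))


@dataclass
class Phantom:
    """3x3 orthogonal-bundle phantom volume with per-voxel ground truth."""

    data: np.ndarray          # (nx, ny, nz, n_meas)
    scheme: AcquisitionScheme
    labels: np.ndarray        # bundle id 0..8, -1 for background
    orientations: np.ndarray  # (9, 3) bundle orientations
    gt_dt6: np.ndarray        # (nx, ny, nz, 6)
    gt_w15: np.ndarray        # (nx, ny, nz, 15)

    @property
    def bundle_mask(self) -> np.ndarray:
        return self.labels >= 0


def orthogonal_phantom(scheme: AcquisitionScheme | None = None,
                       depth: int = 3) -> Phantom:
    """Noise-free phantom: nine fiber bundles in a 3x3 grid, three bundles
    along each of x, y, z, surrounded by free water.

    Mimics one low-resolution imaging voxel with orthogonal fiber content
    while each bundle remains individually resolvable.  Signals follow the
    DKI forward model of each voxel's exact cumulants.
    """
    if scheme is None:
        # phantom-style shell spacing, capped at the b <= 3 ms/um^2 range
        # where the quadratic cumulant expansion is trustworthy for
        # brain-strength kurtosis
        from .directions import load_directions
        scheme = AcquisitionScheme.multi_shell(
            [0.5, 1.0, 1.8, 2.5, 3.0], load_directions("15"))
    nx = ny = 5
    nz = depth
    axes = np.eye(3)
    labels = np.full((nx, ny, nz), -1, dtype=int)
    orientations = np.empty((9, 3))
    gt_dt6 = np.empty((nx, ny, nz, 6))
    gt_w15 = np.zeros((nx, ny, nz, 15))
    water = DiffusionTensor.isotropic(FREE_WATER_DIFFUSIVITY)
    gt_dt6[...] = water.components

    for i in range(3):
        for j in range(3):
            bundle = 3 * i + j
            u = axes[(i + j) % 3]
            orientations[bundle] = u
            d, w = mixture_cumulants(default_fiber_kernel(u))
            labels[i + 1, j + 1, :] = bundle
            gt_dt6[i + 1, j + 1, :] = d.components
            gt_w15[i + 1, j + 1, :] = w.components

    flat_d = gt_dt6.reshape(-1, 6)
    flat_w = gt_w15.reshape(-1, 15)
    data = predict_signal_many(flat_d, flat_w, scheme).reshape(
        nx, ny, nz, len(scheme))
    return Phantom(data, scheme, labels, orientations, gt_dt6, gt_w15)
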
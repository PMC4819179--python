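"""Evaluation procedures: proxy-vs-KFA sweeps, b-value optimization,
fiber-mixing curves, averaging experiments, SNR and contrast utilities.

The central question these procedures answer is when the cheap two-shell
KFA proxy (std/rms of per-direction apparent kurtosis) tracks the true,
tensor-derived KFA.  Sweeps simulate two-shell acquisitions from a voxel
population's exact (D, W), add Rician noise, estimate the proxy per voxel,
and average the per-realization Pearson correlation with true KFA over
noise realizations — never the correlation of pooled samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .directions import load_directions
from .exceptions import (
    InvalidInputError,
    InvalidParameterError,
    UndefinedCorrelationError,
)
from .model import AcquisitionScheme, DKIModel, predict_signal_many
from .proxy import TwoShellScheme, _proxy_from_signals
from .simulate import (
    DEFAULT_ALPHAS,
    NoiseSpec,
    Population,
    default_fiber_kernel,
    mix_signals,
    volume_fraction_index,
)

__all__ = [
    "SweepResult", "pearson", "direction_snr_sweep", "bvalue_grid_search",
    "mixture_sweep", "average_then_fit", "rms_contrast", "estimate_snr",
    "fa_segmentation",
]

#: Rayleigh std of unit-sigma complex Gaussian noise magnitude
RAYLEIGH_STD_FACTOR = float(np.sqrt(2.0 - np.pi / 2.0))

#: default two-shell b-values (ms/um^2) for proxy simulations
DEFAULT_B1, DEFAULT_B2 = 1.0, 2.5

#: default direction counts for proxy sweeps
DEFAULT_DIRECTION_COUNTS = (3, 5, 9, 15, 25, 36, 46, 65, 86)

#: default b-value search grid (ms/um^2)
DEFAULT_B_GRID = np.round(np.arange(0.2, 6.01, 0.2), 10)


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson linear correlation coefficient."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size < 3:
        raise InvalidInputError("need equal-length vectors of size >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance input")
    return float(stats.pearsonr(x, y).statistic)


@dataclass
class SweepResult:
    """Grid of realization-averaged proxy-KFA correlations."""

    axis1_name: str
    axis1: np.ndarray
    axis2_name: str
    axis2: np.ndarray
    mean_r: np.ndarray       # (len(axis1), len(axis2)), nan where masked
    sd_r: np.ndarray
    n_realizations: int
    seed: int
    flagged: np.ndarray = field(default=None)  # >50% invalid voxels

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.axis1):
            for j, b in enumerate(self.axis2):
                rows.append({self.axis1_name: a, self.axis2_name: b,
                             "mean_r": self.mean_r[i, j],
                             "sd_r": self.sd_r[i, j],
                             "n": self.n_realizations})
        return pd.DataFrame(rows)

    def argmax(self) -> tuple:
        """(axis1 value, axis2 value) of the best mean correlation."""
        idx = np.unravel_index(np.nanargmax(self.mean_r), self.mean_r.shape)
        return self.axis1[idx[0]], self.axis2[idx[1]]


def _two_shell_signals(dt6, w15, directions, b1, b2):
    """Noise-free (n_vox, 1 + 2N) block in proxy_map measurement order."""
    scheme = TwoShellScheme(b1, b2, directions).to_acquisition()
    return predict_signal_many(dt6, w15, scheme)


def _mean_proxy_correlation(dt6, w15, kfa_true, directions, b1, b2,
                            snr, n_realizations, rng_seed, cell_key):
    """Mean/sd of per-realization Pearson r, plus invalid-voxel fraction."""
    clean = _two_shell_signals(dt6, w15, directions, b1, b2)
    if np.isinf(snr):
        n_realizations = 1
    rs = []
    bad_frac = 0.0
    for k in range(n_realizations):
        if np.isinf(snr):
            noisy = clean
        else:
            rng = np.random.default_rng(np.random.SeedSequence(
                entropy=int(rng_seed), spawn_key=tuple(cell_key) + (k,)))
            g1 = rng.standard_normal(clean.shape)
            g2 = rng.standard_normal(clean.shape)
            sigma = 1.0 / snr
            noisy = np.sqrt((clean + sigma * g1) ** 2 + (sigma * g2) ** 2)
        n = directions.shape[0]
        proxy, valid = _proxy_from_signals(
            noisy[:, 0], noisy[:, 1:1 + n], noisy[:, 1 + n:], b1, b2)
        ok = valid & np.isfinite(proxy)
        bad_frac = max(bad_frac, 1.0 - ok.mean())
        if ok.sum() < 3 or np.ptp(kfa_true[ok]) == 0:
            rs.append(np.nan)
        else:
            rs.append(pearson(proxy[ok], kfa_true[ok]))
    rs = np.asarray(rs)
    return (float(np.nanmean(rs)), float(np.nanstd(rs)), bad_frac)


def direction_snr_sweep(population: Population,
                        direction_counts=DEFAULT_DIRECTION_COUNTS,
                        snr_levels=(20, 40, 60, 80, 100, np.inf),
                        b1: float = DEFAULT_B1, b2: float = DEFAULT_B2,
                        spec: NoiseSpec | None = None) -> SweepResult:
    """Proxy-KFA correlation over (direction count x SNR) cells.

    For each cell: simulate b=0 plus two shells from every voxel's exact
    (D, W), add Rician noise (``spec.n_realizations`` realizations), compute
    the per-voxel proxy, correlate with true KFA, and average r over
    realizations.  Infinite SNR runs a single noise-free realization.
    """
    if spec is None:
        spec = NoiseSpec(snr=100, n_realizations=100, seed=0)
    if len(population) < 50 or np.ptp(population.kfa) == 0 or \
            np.var(population.kfa) == 0:
        raise InvalidInputError(
            "population must have >= 50 voxels with KFA variance > 0")
    counts = list(direction_counts)
    snrs = list(snr_levels)
    mean_r = np.full((len(counts), len(snrs)), np.nan)
    sd_r = np.full_like(mean_r, np.nan)
    flagged = np.zeros(mean_r.shape, dtype=bool)
    for i, n_dir in enumerate(counts):
        dirs = load_directions(str(n_dir))
        for j, snr in enumerate(snrs):
            m, s, bad = _mean_proxy_correlation(
                population.dt6, population.w15, population.kfa, dirs,
                b1, b2, snr, spec.n_realizations, spec.seed,
                cell_key=(0, i, j))
            mean_r[i, j], sd_r[i, j] = m, s
            flagged[i, j] = bad > 0.5
    return SweepResult("n_directions", np.array(counts), "snr",
                       np.array(snrs, dtype=float), mean_r, sd_r,
                       spec.n_realizations, spec.seed, flagged)


def bvalue_grid_search(population: Population,
                       b1_grid=DEFAULT_B_GRID, b2_grid=DEFAULT_B_GRID,
                       n_directions: int = 9, snr: float = 100,
                       spec: NoiseSpec | None = None,
                       n_voxels: int = 125) -> SweepResult:
    """Proxy-KFA correlation over a (b1 x b2) grid; b1 >= b2 cells masked.

    Uses a random subsample of ``n_voxels`` voxels (mirroring estimation
    from a modest set of pixels); returns the full grid with nan in masked
    cells.  ``SweepResult.argmax()`` gives the best (b1, b2).
    """
    if spec is None:
        spec = NoiseSpec(snr=snr, n_realizations=100, seed=0)
    b1_grid = np.asarray(b1_grid, dtype=float)
    b2_grid = np.asarray(b2_grid, dtype=float)
    if not np.any(b1_grid[:, None] < b2_grid[None, :]):
        raise InvalidParameterError("grid contains no valid b1 < b2 cell")
    rng = np.random.default_rng(spec.seed)
    if n_voxels < len(population):
        idx = rng.choice(len(population), size=n_voxels, replace=False)
    else:
        idx = np.arange(len(population))
    dt6 = population.dt6[idx]
    w15 = population.w15[idx]
    kfa_true = population.kfa[idx]
    dirs = load_directions(str(n_directions))
    mean_r = np.full((len(b1_grid), len(b2_grid)), np.nan)
    sd_r = np.full_like(mean_r, np.nan)
    flagged = np.zeros(mean_r.shape, dtype=bool)
    for i, b1 in enumerate(b1_grid):
        for j, b2 in enumerate(b2_grid):
            if not b1 < b2:
                continue
            m, s, bad = _mean_proxy_correlation(
                dt6, w15, kfa_true, dirs, b1, b2, spec.snr,
                spec.n_realizations, spec.seed, cell_key=(1, i, j))
            mean_r[i, j], sd_r[i, j] = m, s
            flagged[i, j] = bad > 0.5
    return SweepResult("b1", b1_grid, "b2", b2_grid, mean_r, sd_r,
                       spec.n_realizations, spec.seed, flagged)


# ---------------------------------------------------------------------------
# fiber mixing (FA-vanishing / KFA-surviving experiment)
# ---------------------------------------------------------------------------

def mixture_sweep(kernels=None, alphas=DEFAULT_ALPHAS,
                  scheme: AcquisitionScheme | None = None,
                  proxy_b1: float = 1.0, proxy_b2: float = 2.4,
                  proxy_directions: int = 9) -> pd.DataFrame:
    """Metric curves versus fiber-mixing level.

    Signals from three orthogonal single-fiber kernels are mixed with
    weights (1-2a, a, a), the DKI model is fitted to each mixture, and the
    metrics MD, FA, Wbar, KFA plus the 9-direction two-shell proxy are
    tabulated against the volume fraction index VI.  Each metric column gets
    a ``<name>_norm`` companion normalized to its per-sweep maximum.
    """
    if kernels is None:
        kernels = [default_fiber_kernel(u) for u in np.eye(3)]
    if len(kernels) != 3:
        raise InvalidInputError("need exactly three orthogonal kernels")
    alphas = np.asarray(alphas, dtype=float)
    if np.any(alphas < 0) or np.any(alphas > 1 / 3 + 1e-12):
        raise InvalidParameterError("alpha grid must lie in [0, 1/3]")
    if scheme is None:
        scheme = AcquisitionScheme.multi_shell(
            np.round(np.arange(0.2, 3.01, 0.2), 10), load_directions("33"))
    proxy_dirs = load_directions(str(proxy_directions))
    proxy_scheme = TwoShellScheme(proxy_b1, proxy_b2, proxy_dirs)
    pacq = proxy_scheme.to_acquisition()

    from .simulate import mixture_cumulants
    blocks, pblocks = [], []
    for k in kernels:
        d, w = mixture_cumulants(k)
        blocks.append(predict_signal_many(d.components, w.components,
                                          scheme)[0])
        pblocks.append(predict_signal_many(d.components, w.components,
                                           pacq)[0])

    rows = []
    for a in alphas:
        mixed = mix_signals(*blocks, a)
        res = DKIModel(mixed, scheme).fit()
        vi = volume_fraction_index(np.array([1 - 2 * a, a, a]))
        pmixed = mix_signals(*pblocks, a)
        n = proxy_scheme.n_directions
        proxy, _ = _proxy_from_signals(pmixed[0], pmixed[1:1 + n],
                                       pmixed[1 + n:], proxy_b1, proxy_b2)
        rows.append({
            "alpha": a, "VI": vi,
            "MD": float(res.md[0]), "FA": float(res.fa[0]),
            "Wbar": float(res.wbar[0]), "KFA": float(res.kfa[0]),
            "proxy": float(proxy),
            "converged": bool(res.converged[0]),
        })
    df = pd.DataFrame(rows)
    for col in ("MD", "FA", "Wbar", "KFA", "proxy"):
        df[f"{col}_norm"] = df[col] / df[col].max()
    return df


# ---------------------------------------------------------------------------
# averaging experiment (phantom analysis)
# ---------------------------------------------------------------------------

def average_then_fit(volume: np.ndarray, mask: np.ndarray,
                     scheme: AcquisitionScheme,
                     method: str = "nlls") -> pd.DataFrame:
    """Signal-average-then-fit vs fit-then-parameter-average over a mask.

    Averaging each diffusion encoding across the mask before fitting mimics
    a low-resolution voxel with sub-voxel fiber heterogeneity; fitting every
    voxel and averaging the parameters gives the true mean.  Returns a
    2-row table (MD, FA, Wbar, KFA) indexed by estimator.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise InvalidInputError("empty mask")
    vox = np.asarray(volume, dtype=float).reshape(-1, len(scheme))
    vox = vox[mask.ravel()]

    res = DKIModel(vox, scheme).fit(method)
    fit_avg = {"MD": float(res.md.mean()), "FA": float(res.fa.mean()),
               "Wbar": float(res.wbar.mean()), "KFA": float(res.kfa.mean())}

    mean_sig = vox.mean(axis=0)
    res2 = DKIModel(mean_sig, scheme).fit(method)
    avg_fit = {"MD": float(res2.md[0]), "FA": float(res2.fa[0]),
               "Wbar": float(res2.wbar[0]), "KFA": float(res2.kfa[0])}
    return pd.DataFrame([fit_avg, avg_fit],
                        index=["fit_then_average", "average_then_fit"])


# ---------------------------------------------------------------------------
# image utilities
# ---------------------------------------------------------------------------

def rms_contrast(scalar_map: np.ndarray) -> float:
    """RMS contrast: std of the min-max-normalized intensities.

    Invariant to positive affine rescaling; 0 for a constant map.
    """
    m = np.asarray(scalar_map, dtype=float).ravel()
    m = m[np.isfinite(m)]
    if m.size == 0:
        raise InvalidInputError("empty map")
    lo, hi = m.min(), m.max()
    if hi == lo:
        return 0.0
    return float(np.std((m - lo) / (hi - lo)))


def estimate_snr(image: np.ndarray, object_mask: np.ndarray,
                 background_mask: np.ndarray) -> float:
    """SNR = mean(object) / Gaussian sigma inferred from background.

    The signal-free background of a magnitude image is Rayleigh distributed
    with std sigma*sqrt(2 - pi/2); dividing the background std by that
    factor recovers the underlying per-channel Gaussian sigma.
    """
    image = np.asarray(image, dtype=float)
    obj = np.asarray(object_mask, bool)
    bg = np.asarray(background_mask, bool)
    if not obj.any() or not bg.any():
        raise InvalidInputError("object and background masks must be non-empty")
    sigma = np.std(image[bg]) / RAYLEIGH_STD_FACTOR
    if sigma == 0:
        raise InvalidInputError("zero background variance: SNR undefined")
    return float(np.mean(image[obj]) / sigma)


def fa_segmentation(fa_map: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """FA-band tissue masks: WM for 0.6 < FA < 1, GM for 0.1 < FA < 0.3.

    Strict inequalities; voxels outside both bands belong to neither mask.
    """
    fa = np.asarray(fa_map, dtype=float)
    wm = (fa > 0.6) & (fa < 1.0)
    gm = (fa > 0.1) & (fa < 0.3)
    return wm, gm
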
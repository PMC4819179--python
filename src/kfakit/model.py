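"""Diffusion kurtosis signal model and voxel-wise estimation.

The log-signal of the DKI model is the b-quadratic cumulant expansion

    ln S(b, n) = ln S0 - b n_i n_j D_ij + (b^2/6) MD^2 n_i n_j n_k n_l W_ijkl

with b in ms/um^2 and D in um^2/ms.  Estimation treats the quartic block
V = MD^2 * W as a single linear group, giving 1 + 6 + 15 = 22 unknowns whose
log-domain problem is exactly linear; the nonlinear least-squares fit (the
default) starts from that linear solution and minimizes residuals of the
exponentiated model with a trust-region solver.  W is recovered by dividing
the fitted quartic coefficients by MD^2 from the same fit.

Fitting follows common DKI practice: signals are normalized to the b = 0
image so fitted values lie in (0, ~1], no positivity or directional-kurtosis
constraints are imposed, and questionable voxels (negative eigenvalues,
strongly negative directional kurtosis) are flagged rather than rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .exceptions import DesignError, InvalidInputError, InvalidSchemeError
from .tensors import (
    DiffusionTensor,
    KurtosisTensor,
    kfa_from_w15,
    md_fa_from_dt6,
    quadratic_design,
    quartic_design,
    wbar_from_w15,
)

__all__ = ["AcquisitionScheme", "DkiFit", "DKIModel", "DKIResults",
           "predict_signal", "fit_dki", "design_matrix"]

#: minimum directional kurtosis admissible for a magnitude-MR signal
K_MIN_PHYSICAL = -3.0 / 7.0


@dataclass(frozen=True)
class AcquisitionScheme:
    """Multi-shell acquisition: per-measurement b-value and unit direction.

    b in ms/um^2 (1 ms/um^2 = 1000 s/mm^2); directions unit-norm except at
    b = 0 where a zero vector is allowed.
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self):
        b = np.asarray(self.bvals, dtype=float).ravel()
        v = np.asarray(self.bvecs, dtype=float)
        if v.ndim != 2 or v.shape[1] != 3:
            raise InvalidSchemeError("bvecs must be an (N, 3) array")
        if b.shape[0] != v.shape[0]:
            raise InvalidSchemeError(
                f"{b.shape[0]} b-values vs {v.shape[0]} directions")
        if not (np.all(np.isfinite(b)) and np.all(np.isfinite(v))):
            raise InvalidSchemeError("non-finite scheme entries")
        if np.any(b < 0):
            raise InvalidSchemeError("negative b-values")
        norms = np.linalg.norm(v, axis=1)
        nonzero = b > 0
        if np.any(np.abs(norms[nonzero] - 1.0) > 1e-6):
            raise InvalidSchemeError(
                "non-unit direction at nonzero b (deviation > 1e-6)")
        if np.any((~nonzero) & (norms > 1e-6) & (np.abs(norms - 1) > 1e-6)):
            # b=0 rows may be zero or unit vectors; anything else is malformed
            raise InvalidSchemeError("malformed b=0 direction row")
        object.__setattr__(self, "bvals", b)
        object.__setattr__(self, "bvecs", v)

    def __len__(self) -> int:
        return self.bvals.shape[0]

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    @property
    def shells(self) -> np.ndarray:
        """Unique nonzero b-values (rounded to 1e-6)."""
        return np.unique(np.round(self.bvals[self.bvals > 0], 6))

    def counts_per_shell(self) -> dict[float, int]:
        out = {0.0: int(self.b0_mask.sum())}
        for s in self.shells:
            out[float(s)] = int(np.sum(np.isclose(self.bvals, s)))
        return out

    @classmethod
    def multi_shell(cls, bvalues, directions) -> "AcquisitionScheme":
        """One b = 0 measurement plus every b in ``bvalues`` x ``directions``."""
        directions = np.asarray(directions, dtype=float)
        bvalues = [b for b in np.atleast_1d(bvalues) if b > 0]
        bvals = [0.0]
        bvecs = [np.zeros(3)]
        for b in bvalues:
            bvals.extend([b] * len(directions))
            bvecs.extend(directions)
        return cls(np.array(bvals), np.array(bvecs))


def design_matrix(scheme: AcquisitionScheme) -> np.ndarray:
    """(N, 22) log-domain design: [1 | -b * n.n | (b^2/6) * quartic(n)]."""
    b = scheme.bvals[:, None]
    quad = -b * quadratic_design(scheme.bvecs)
    quart = (b ** 2 / 6.0) * quartic_design(scheme.bvecs)
    return np.hstack([np.ones((len(scheme), 1)), quad, quart])


def predict_signal(s0, d, w, scheme: AcquisitionScheme) -> np.ndarray:
    """Forward DKI signal for one voxel over ``scheme``.

    ``d`` and ``w`` may be tensor objects or raw 6-/15-component arrays.
    Returns S0 exactly at b = 0.
    """
    dt6 = d.components if isinstance(d, DiffusionTensor) else np.asarray(d, float)
    w15 = w.components if isinstance(w, KurtosisTensor) else np.asarray(w, float)
    if not np.isscalar(s0) or s0 <= 0:
        s0 = float(s0)
        if s0 <= 0:
            raise InvalidInputError("S0 must be positive")
    md = dt6[:3].sum() / 3.0
    beta = np.concatenate([[np.log(s0)], dt6, md * md * w15])
    return np.exp(design_matrix(scheme) @ beta)


def predict_signal_many(dt6: np.ndarray, w15: np.ndarray,
                        scheme: AcquisitionScheme,
                        s0: float = 1.0) -> np.ndarray:
    """Vectorized forward model: (n_voxels, 6)+(n_voxels, 15) -> (n_voxels, N)."""
    dt6 = np.atleast_2d(np.asarray(dt6, float))
    w15 = np.atleast_2d(np.asarray(w15, float))
    md = dt6[:, :3].sum(axis=1) / 3.0
    a = design_matrix(scheme)
    beta = np.hstack([np.full((dt6.shape[0], 1), np.log(s0)),
                      dt6, md[:, None] ** 2 * w15])
    return np.exp(beta @ a.T)


@dataclass
class DkiFit:
    """Single-voxel fit result (functional API)."""

    s0: float
    diffusion: DiffusionTensor
    kurtosis: KurtosisTensor
    residual_norm: float
    converged: bool
    qc_flags: dict = field(default_factory=dict)


def _validate_design(scheme: AcquisitionScheme, a: np.ndarray) -> None:
    n = len(scheme)
    if n < 22:
        raise DesignError(f"{n} measurements cannot determine 22 unknowns")
    nb = len(np.unique(np.round(scheme.bvals, 6)))
    if nb < 3 or not np.any(scheme.b0_mask):
        raise DesignError(
            "need >= 3 distinct b-values including b = 0 "
            f"(got {nb}, b0 present: {bool(np.any(scheme.b0_mask))})")
    if np.linalg.matrix_rank(a) < 22:
        raise DesignError("rank-deficient design (directions not of full "
                          "rank for both tensor orders)")


class DKIModel:
    """Voxel-wise DKI estimation, statsmodels-style.

    Parameters
    ----------
    signals : array, shape (n_meas,) or (n_voxels, n_meas)
        Raw (unnormalized) signals aligned with ``scheme``.
    scheme : AcquisitionScheme

    Examples
    --------
    >>> model = DKIModel(signals, scheme)
    >>> res = model.fit()          # nonlinear least squares
    >>> res.kfa, res.fa, res.md    # per-voxel metric arrays
    >>> print(res.summary())
    """

    def __init__(self, signals: np.ndarray, scheme: AcquisitionScheme):
        sig = np.asarray(signals, dtype=float)
        squeeze = sig.ndim == 1
        sig = np.atleast_2d(sig)
        if sig.shape[1] != len(scheme):
            raise InvalidInputError(
                f"signals have {sig.shape[1]} measurements, scheme has "
                f"{len(scheme)}")
        if not np.all(np.isfinite(sig)):
            raise InvalidInputError("non-finite signals")
        if np.any(sig < 0):
            raise InvalidInputError("negative signals")
        self.signals = sig
        self.scheme = scheme
        self._squeeze = squeeze
        self.design = design_matrix(scheme)

    @classmethod
    def from_bundle(cls, bundle, mask: np.ndarray | None = None) -> "DKIModel":
        """Build from an :class:`~kfakit.io.DatasetBundle` (4-D volume)."""
        data = bundle.data
        vox = data.reshape(-1, data.shape[-1])
        if mask is not None:
            vox = vox[np.asarray(mask, bool).ravel()]
        return cls(vox, bundle.scheme)

    # -- estimation ---------------------------------------------------------

    def fit(self, method: str = "nlls", xtol: float = 1e-10,
            ftol: float = 1e-10, max_iter: int = 500) -> "DKIResults":
        """Fit (S0, D, W) per voxel.

        ``method='nlls'`` (default): trust-region nonlinear least squares on
        the exponentiated model, initialized from the exact linear log-domain
        solution.  ``method='wls'``: signal-squared-weighted linear fit of
        the log signal (fast fallback for large sweeps).
        """
        if method not in ("nlls", "wls"):
            raise InvalidInputError(f"unknown fit method {method!r}")
        a = self.design
        _validate_design(self.scheme, a)
        n_vox = self.signals.shape[0]
        b0 = self.scheme.b0_mask

        betas = np.empty((n_vox, 22))
        resid = np.empty(n_vox)
        conv = np.zeros(n_vox, dtype=bool)
        s0_obs = self.signals[:, b0].mean(axis=1)

        for i in range(n_vox):
            s0i = s0_obs[i]
            if s0i <= 0:
                betas[i] = np.nan
                resid[i] = np.nan
                continue
            y = self.signals[i] / s0i
            logy = np.log(np.clip(y, 1e-10, None))
            wts = y  # ~1/sd of log-signal under additive noise
            beta0, *_ = np.linalg.lstsq(a * wts[:, None], logy * wts,
                                        rcond=None)
            if method == "wls":
                betas[i] = beta0
                resid[i] = float(np.linalg.norm(np.exp(a @ beta0) - y))
                conv[i] = True
                continue

            def fun(beta, y=y):
                return np.exp(a @ beta) - y

            def jac(beta):
                return np.exp(a @ beta)[:, None] * a

            sol = least_squares(fun, beta0, jac=jac, method="trf",
                                xtol=xtol, ftol=ftol, gtol=1e-12,
                                max_nfev=max_iter)
            betas[i] = sol.x
            resid[i] = float(np.linalg.norm(sol.fun))
            conv[i] = bool(sol.status > 0)

        s0 = np.exp(betas[:, 0]) * s0_obs
        dt6 = betas[:, 1:7]
        quart = betas[:, 7:]
        md = dt6[:, :3].sum(axis=1) / 3.0
        with np.errstate(invalid="ignore", divide="ignore"):
            w15 = np.where(md[:, None] ** 2 > 1e-20,
                           quart / np.maximum(md[:, None] ** 2, 1e-20), 0.0)
        return DKIResults(self, s0=s0, dt6=dt6, w15=w15,
                          residual_norm=resid, converged=conv, method=method)


class DKIResults:
    """Per-voxel DKI estimates with scalar metrics and QC flags.

    Attributes are arrays over voxels: ``s0``, ``dt6`` (6 unique D
    components), ``w15`` (15 unique W components), ``residual_norm``,
    ``converged``.  Scalar metrics are lazy properties.
    """

    def __init__(self, model: DKIModel, s0, dt6, w15, residual_norm,
                 converged, method: str):
        self.model = model
        self.s0 = s0
        self.dt6 = dt6
        self.w15 = w15
        self.residual_norm = residual_norm
        self.converged = converged
        self.method = method

    @property
    def n_voxels(self) -> int:
        return self.dt6.shape[0]

    @property
    def md(self) -> np.ndarray:
        return md_fa_from_dt6(self.dt6)[0]

    @property
    def fa(self) -> np.ndarray:
        return md_fa_from_dt6(self.dt6)[1]

    @property
    def wbar(self) -> np.ndarray:
        return wbar_from_w15(self.w15)

    @property
    def kfa(self) -> np.ndarray:
        return kfa_from_w15(self.w15)

    def mk(self, directions: np.ndarray | None = None) -> np.ndarray:
        """Mean kurtosis per voxel by spherical averaging of K(n)."""
        if directions is None:
            from .directions import quadrature_set
            directions = quadrature_set()
        dn = quadratic_design(directions) @ self.dt6.T
        wn = quartic_design(directions) @ self.w15.T
        md = self.md
        with np.errstate(invalid="ignore", divide="ignore"):
            k = md[None, :] ** 2 / dn ** 2 * wn
        return k.mean(axis=0)

    # -- QC -----------------------------------------------------------------

    @property
    def qc_negative_eigenvalue(self) -> np.ndarray:
        """True where the fitted D has a negative eigenvalue."""
        eigs = np.linalg.eigvalsh(self._matrices())
        return eigs[:, 0] < 0

    @property
    def qc_unphysical_kurtosis(self) -> np.ndarray:
        """True where min over fit directions of K(n) < -3/7."""
        nz = ~self.model.scheme.b0_mask
        dirs = self.model.scheme.bvecs[nz]
        dirs = np.unique(np.round(dirs, 12), axis=0)
        dn = quadratic_design(dirs) @ self.dt6.T
        wn = quartic_design(dirs) @ self.w15.T
        md = self.md
        with np.errstate(invalid="ignore", divide="ignore"):
            k = md[None, :] ** 2 / dn ** 2 * wn
        return np.nanmin(k, axis=0) < K_MIN_PHYSICAL

    def _matrices(self) -> np.ndarray:
        c = self.dt6
        return np.stack([
            np.stack([c[:, 0], c[:, 3], c[:, 4]], axis=-1),
            np.stack([c[:, 3], c[:, 1], c[:, 5]], axis=-1),
            np.stack([c[:, 4], c[:, 5], c[:, 2]], axis=-1),
        ], axis=-2)

    # -- presentation -------------------------------------------------------

    def diffusion_tensor(self, i: int = 0) -> DiffusionTensor:
        return DiffusionTensor(self.dt6[i])

    def kurtosis_tensor(self, i: int = 0) -> KurtosisTensor:
        return KurtosisTensor(self.w15[i])

    def metrics_frame(self) -> pd.DataFrame:
        """Per-voxel metric table (MD, FA, Wbar, KFA + diagnostics)."""
        return pd.DataFrame({
            "MD": self.md, "FA": self.fa, "Wbar": self.wbar,
            "KFA": self.kfa, "S0": self.s0,
            "residual": self.residual_norm, "converged": self.converged,
            "neg_eig": self.qc_negative_eigenvalue,
        })

    def summary(self) -> str:
        df = self.metrics_frame()
        lines = [
            "DKI fit summary",
            "===============",
            f"voxels: {self.n_voxels}   method: {self.method}   "
            f"measurements: {len(self.model.scheme)}   "
            f"shells: {[round(float(s), 4) for s in self.model.scheme.shells]}",
            f"converged: {int(self.converged.sum())}/{self.n_voxels}   "
            f"neg-eigenvalue flags: {int(df.neg_eig.sum())}",
            "",
            df[["MD", "FA", "Wbar", "KFA"]].describe().loc[
                ["mean", "std", "min", "50%", "max"]].to_string(
                float_format=lambda v: f"{v:8.4f}"),
        ]
        return "\n".join(lines)

    def to_fit(self, i: int = 0) -> DkiFit:
        return DkiFit(
            s0=float(self.s0[i]),
            diffusion=self.diffusion_tensor(i),
            kurtosis=self.kurtosis_tensor(i),
            residual_norm=float(self.residual_norm[i]),
            converged=bool(self.converged[i]),
            qc_flags={
                "negative_eigenvalue": bool(self.qc_negative_eigenvalue[i]),
                "unphysical_kurtosis": bool(self.qc_unphysical_kurtosis[i]),
            },
        )


def fit_dki(signals: np.ndarray, scheme: AcquisitionScheme,
            method: str = "nlls") -> DkiFit:
    """Fit a single voxel; see :class:`DKIModel` for the estimation details."""
    res = DKIModel(np.asarray(signals, float).ravel(), scheme).fit(method)
    return res.to_fit(0)
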
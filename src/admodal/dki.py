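"""Diffusion kurtosis imaging: Rician floor adjustment, voxelwise DKI fit,
MD/FA/MK maps, and ROI summaries with whole-brain-normalized volumetrics.

The DKI signal equation extends the diffusion tensor model with a fully
symmetric rank-4 kurtosis tensor W::

    ln S(b, n) = ln S0 - b * D_app(n) + (b^2 / 6) * MD^2 * W_app(n)

with D_app(n) = n^T D n, W_app(n) = sum_ijkl n_i n_j n_k n_l W_ijkl, and
MD = tr(D)/3. Units: b in ms/um^2, D in um^2/ms, W dimensionless. The
apparent kurtosis along n is K_app(n) = (MD^2 / D_app(n)^2) * W_app(n); MK is
K_app averaged over a dense direction set.

Fitting is the standard two-stage scheme: weighted linear least squares on
the log signal (weights = squared predicted signal, the delta-method
correction for log-transform heteroscedasticity) initializes, then nonlinear
least squares on the exponentiated model refines, with the apparent kurtosis
softly penalized into configured bounds and D projected to the nearest
symmetric positive-definite matrix if the initializer strays.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement, permutations
from math import factorial

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "GradientScheme",
    "DKIFit",
    "DKIMetrics",
    "study_scheme",
    "rician_floor_adjust",
    "build_design",
    "fit_dki_voxel",
    "fit_dki_volume",
    "metrics",
    "summarize_rois",
    "sphere_directions",
]

# unique-element bookkeeping for the symmetric tensors ----------------------

#: order of the 6 unique D elements
D_IDX = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]
#: symmetry multiplicity of each unique D element
D_MULT = np.array([1.0, 1.0, 1.0, 2.0, 2.0, 2.0])
#: order of the 15 unique W elements (sorted index 4-tuples)
W_IDX = list(combinations_with_replacement(range(3), 4))


def _w_mult(idx: tuple[int, ...]) -> float:
    c = [idx.count(ax) for ax in range(3)]
    return factorial(4) / (factorial(c[0]) * factorial(c[1]) * factorial(c[2]))


W_MULT = np.array([_w_mult(ix) for ix in W_IDX])


def d_to_unique(D: np.ndarray) -> np.ndarray:
    return np.array([D[i, j] for i, j in D_IDX])


def unique_to_d(d6: np.ndarray) -> np.ndarray:
    D = np.empty((3, 3))
    for v, (i, j) in zip(d6, D_IDX):
        D[i, j] = D[j, i] = v
    return D


def w_to_unique(W: np.ndarray) -> np.ndarray:
    return np.array([W[ix] for ix in W_IDX])


def unique_to_w(w15: np.ndarray) -> np.ndarray:
    W = np.zeros((3, 3, 3, 3))
    for v, ix in zip(w15, W_IDX):
        for p in set(permutations(ix)):
            W[p] = v
    return W


# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GradientScheme:
    """Diffusion acquisition scheme: b-values (ms/um^2) + unit directions."""

    b_values: np.ndarray
    directions: np.ndarray  # (M, 3)

    def __post_init__(self) -> None:
        b = np.asarray(self.b_values, dtype=float)
        g = np.asarray(self.directions, dtype=float)
        object.__setattr__(self, "b_values", b)
        object.__setattr__(self, "directions", g)
        if b.ndim != 1 or g.shape != (b.size, 3):
            raise ValueError("b_values (M,) and directions (M,3) must align")
        if np.any(b < 0):
            raise ValueError("negative b-value")
        if not np.any(b == 0):
            raise ValueError("scheme needs at least one b=0 measurement")
        dwi = b > 0
        norms = np.linalg.norm(g[dwi], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("diffusion directions must be unit vectors")

    def __len__(self) -> int:
        return self.b_values.size

    @classmethod
    def from_fsl(cls, bval_path, bvec_path, b_units: str = "ms/um^2"):
        """Read FSL-style .bval/.bvec. ``b_units='s/mm^2'`` rescales by 1e-3."""
        b = np.loadtxt(bval_path).ravel()
        g = np.loadtxt(bvec_path)
        if g.shape[0] == 3:
            g = g.T
        if b_units == "s/mm^2":
            b = b * 1e-3
        elif b_units != "ms/um^2":
            raise ValueError(f"unknown b_units {b_units!r}")
        norms = np.linalg.norm(g, axis=1)
        nz = norms > 0
        g = g.copy()
        g[nz] = g[nz] / norms[nz, None]
        return cls(b, g)

    def to_fsl(self, bval_path, bvec_path) -> None:
        np.savetxt(bval_path, self.b_values[None, :], fmt="%.6g")
        np.savetxt(bvec_path, self.directions.T, fmt="%.8f")


def sphere_directions(n: int = 256) -> np.ndarray:
    """Deterministic, nearly uniform unit vectors (spherical Fibonacci)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


#: the study shells in ms/um^2
STUDY_BVALS = (0.4, 0.8, 1.5, 2.0)


def study_scheme(n_b0: int = 5, n_dirs: int = 30,
                 shells: tuple[float, ...] = STUDY_BVALS) -> GradientScheme:
    """The acquisition design used throughout: 5 b0 + 4 shells x 30
    isotropically distributed directions, b = 0.4/0.8/1.5/2.0 ms/um^2."""
    dirs = sphere_directions(n_dirs)
    b = np.concatenate([np.zeros(n_b0)] + [np.full(n_dirs, s) for s in shells])
    g = np.vstack([np.zeros((n_b0, 3))] + [dirs for _ in shells])
    return GradientScheme(b, g)


@dataclass
class DKIFit:
    """Voxel fit: S0, diffusion tensor D (um^2/ms), kurtosis tensor W."""

    S0: float
    D: np.ndarray  # (3, 3) symmetric
    W: np.ndarray  # (3, 3, 3, 3) fully symmetric
    converged: bool = True
    note: str | None = None

    @property
    def md(self) -> float:
        return float(np.trace(self.D) / 3.0)


@dataclass(frozen=True)
class DKIMetrics:
    MD: float
    FA: float
    MK: float


# ---------------------------------------------------------------------------
# operations


def rician_floor_adjust(signal: np.ndarray, sigma: float,
                        k: float = 1.0) -> np.ndarray:
    """Method-of-moments removal of the Rician noise floor.

    adjusted = sqrt(max(S^2 - k * sigma^2, 0)). The default k=1 subtracts one
    noise variance; ``k=2`` implements the alternative E[S^2] = A^2 + 2sigma^2
    moment identity (both conventions are in circulation).
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    s = np.asarray(signal, dtype=float)
    return np.sqrt(np.maximum(s * s - k * sigma * sigma, 0.0))


def _dir_coeffs(g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-direction regressor coefficients for the 6 D and 15 W uniques."""
    dcoef = np.stack([D_MULT[k] * g[:, i] * g[:, j]
                      for k, (i, j) in enumerate(D_IDX)], axis=1)
    wcoef = np.stack(
        [W_MULT[k] * g[:, ix[0]] * g[:, ix[1]] * g[:, ix[2]] * g[:, ix[3]]
         for k, ix in enumerate(W_IDX)], axis=1)
    return dcoef, wcoef


def build_design(scheme: GradientScheme) -> np.ndarray:
    """Design matrix of the log-linear DKI model.

    Columns: [ln S0, 6 D elements, 15 V elements] where V = MD^2 * W is the
    scaled kurtosis tensor estimated linearly (MD is unknown before the fit;
    W is recovered afterwards as V / MD^2). Row for measurement (b, n):
    [1, -b * D-coeffs(n), (b^2/6) * W-coeffs(n)]; b=0 rows carry only the
    intercept. Raises if the scheme cannot identify all 22 parameters.
    """
    b = scheme.b_values
    dcoef, wcoef = _dir_coeffs(scheme.directions)
    X = np.hstack([
        np.ones((len(scheme), 1)),
        -b[:, None] * dcoef,
        (b[:, None] ** 2 / 6.0) * wcoef,
    ])
    if np.linalg.matrix_rank(X) < 22:
        raise ValueError(
            "under-determined scheme: need 22 independent measurements "
            "(>=2 shells and enough distinct directions)"
        )
    return X


def _predict_ln(params: np.ndarray, X: np.ndarray) -> np.ndarray:
    """ln-signal for theta = (lnS0, d6, w15), with the MD^2 factor applied."""
    d6, w15 = params[1:7], params[7:22]
    md = (d6[0] + d6[1] + d6[2]) / 3.0
    theta_lin = np.concatenate([[params[0]], d6, md * md * w15])
    return X @ theta_lin


def _project_spd(D: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    vals, vecs = np.linalg.eigh(0.5 * (D + D.T))
    return (vecs * np.maximum(vals, floor)) @ vecs.T


def fit_dki_voxel(
    signals: np.ndarray,
    scheme: GradientScheme,
    design: np.ndarray | None = None,
    k_bounds: tuple[float, float] = (0.0, 10.0),
    penalty_weight: float = 10.0,
    max_nfev: int = 300,
) -> DKIFit:
    """Fit the DKI signal equation to one voxel.

    Weighted linear LS on the log signal initializes (weights = squared
    predicted signal); nonlinear least squares on S0*exp(model) refines.
    Apparent kurtosis outside ``k_bounds`` on the acquisition directions is
    discouraged by a soft quadratic penalty. Non-positive signals are masked;
    an all-zero voxel returns a flagged null fit rather than raising.
    """
    s = np.asarray(signals, dtype=float)
    if s.shape != (len(scheme),):
        raise ValueError("signal length does not match scheme")
    if not np.any(s > 0):
        return DKIFit(0.0, np.zeros((3, 3)), np.zeros((3, 3, 3, 3)),
                      converged=False, note="all-zero voxel")
    X = build_design(scheme) if design is None else design
    pos = s > 0
    if pos.sum() < 22:
        return DKIFit(0.0, np.zeros((3, 3)), np.zeros((3, 3, 3, 3)),
                      converged=False, note="too few positive samples")
    y = np.log(s[pos])
    Xp = X[pos]
    # two-pass WLS: OLS predictions feed the delta-method weights
    beta = np.linalg.lstsq(Xp, y, rcond=None)[0]
    for _ in range(2):
        w = np.exp(Xp @ beta)  # predicted signal
        Xw = Xp * w[:, None]
        beta = np.linalg.lstsq(Xw, y * w, rcond=None)[0]
    D0 = _project_spd(unique_to_d(beta[1:7]))
    md0 = max(np.trace(D0) / 3.0, 1e-6)
    w15 = beta[7:22] / md0**2
    theta0 = np.concatenate([[beta[0]], d_to_unique(D0), w15])

    b = scheme.b_values[pos]
    dcoef, wcoef = _dir_coeffs(scheme.directions[pos])
    dwi = b > 0
    lo, hi = k_bounds

    def resid(theta):
        ln_pred = _predict_ln(theta, Xp)
        r = np.exp(ln_pred) - s[pos]
        d6, w15 = theta[1:7], theta[7:22]
        md = (d6[0] + d6[1] + d6[2]) / 3.0
        dapp = dcoef[dwi] @ d6
        wapp = wcoef[dwi] @ w15
        kapp = md * md * wapp / np.maximum(dapp * dapp, 1e-12)
        pen = penalty_weight * (np.maximum(kapp - hi, 0.0)
                                + np.maximum(lo - kapp, 0.0))
        return np.concatenate([r, pen])

    sol = least_squares(resid, theta0, method="trf", max_nfev=max_nfev,
                        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    theta = sol.x
    D = unique_to_d(theta[1:7])
    converged = bool(sol.status > 0)
    return DKIFit(float(np.exp(theta[0])), D, unique_to_w(theta[7:22]),
                  converged=converged,
                  note=None if converged else "max iterations reached")


def fit_dki_volume(volume: np.ndarray, scheme: GradientScheme,
                   mask: np.ndarray | None = None,
                   **options) -> dict[str, np.ndarray]:
    """Voxelwise DKI fit over a 4D volume; returns MD/FA/MK/S0 maps.

    ``mask`` restricts fitting; unfitted voxels are NaN. A boolean
    ``converged`` map flags voxels where the optimizer hit its budget.
    """
    if volume.ndim != 4 or volume.shape[-1] != len(scheme):
        raise ValueError("expected (x, y, z, M) volume matching the scheme")
    shape = volume.shape[:3]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    design = build_design(scheme)
    dirs = sphere_directions(256)
    out = {k: np.full(shape, np.nan) for k in ("MD", "FA", "MK", "S0")}
    out["converged"] = np.zeros(shape, dtype=bool)
    for idx in np.argwhere(mask):
        fit = fit_dki_voxel(volume[tuple(idx)], scheme, design=design, **options)
        if fit.S0 == 0.0:
            continue
        m = metrics(fit, mk_directions=dirs)
        i, j, k = idx
        out["MD"][i, j, k] = m.MD
        out["FA"][i, j, k] = m.FA
        out["MK"][i, j, k] = m.MK
        out["S0"][i, j, k] = fit.S0
        out["converged"][i, j, k] = fit.converged
    return out


def metrics(fit: DKIFit, mk_directions: np.ndarray | None = None) -> DKIMetrics:
    """MD, FA, and MK from a voxel fit.

    MK averages the apparent kurtosis K_app(n) = (MD^2/D_app^2) W_app over
    ``mk_directions`` (default: 256-point spherical Fibonacci set, making the
    metric independent of the acquisition directions).
    """
    D = fit.D
    if not np.any(D):
        raise ValueError("zero diffusion tensor")
    lam = np.linalg.eigvalsh(D)
    md = float(lam.mean())
    den = np.sum(lam**2)
    fa = float(np.sqrt(1.5 * np.sum((lam - md) ** 2) / den)) if den > 0 else 0.0
    g = sphere_directions(256) if mk_directions is None else np.asarray(mk_directions)
    dcoef, wcoef = _dir_coeffs(g)
    dapp = dcoef @ d_to_unique(D)
    wapp = wcoef @ w_to_unique(fit.W)
    kapp = md * md * wapp / np.maximum(dapp * dapp, 1e-20)
    return DKIMetrics(MD=md, FA=fa, MK=float(kapp.mean()))


def summarize_rois(
    metric_maps: dict[str, np.ndarray],
    roi_masks: dict[str, np.ndarray],
    brain_mask: np.ndarray,
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> pd.DataFrame:
    """Per-ROI metric means and whole-brain-normalized volumes.

    Hemisphere pooling is the caller's responsibility (pass pooled masks).
    ``relative_volume`` = ROI voxels / whole-brain voxels; the voxel volume
    cancels in the ratio but absolute volume (mm^3) is also reported.
    """
    brain_vox = int(np.count_nonzero(brain_mask))
    if brain_vox == 0:
        raise ValueError("empty whole-brain mask")
    vox_vol = float(np.prod(voxel_size_mm))
    rows = []
    for label, m in roi_masks.items():
        if m.shape != brain_mask.shape:
            raise ValueError(f"ROI {label!r} shape mismatch")
        nv = int(np.count_nonzero(m))
        if nv == 0:
            raise ValueError(f"empty ROI mask {label!r}")
        rec = {"roi": label, "n_voxels": nv,
               "volume_mm3": nv * vox_vol,
               "relative_volume": nv / brain_vox}
        for name, vol in metric_maps.items():
            vals = vol[m.astype(bool)]
            rec[f"mean_{name}"] = float(np.nanmean(vals))
        rows.append(rec)
    return pd.DataFrame(rows)
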
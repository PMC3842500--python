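"""Constrained spherical deconvolution (CSD) of single-shell DWI signal.

The diffusion signal in a voxel is modelled as the spherical convolution of
an axially symmetric single-fibre response function R with the voxel's fibre
orientation distribution (FOD).  On the real even-order SH basis the
convolution is diagonal per degree l:

    s_lm = f_lm * k_l,      k_l = sqrt(4 pi / (2l + 1)) * r_l,

with r_l the zonal (m = 0) SH coefficients of R aligned with +z.  The FOD is
recovered by linear deconvolution regularised with an iteratively re-weighted
soft non-negativity constraint: amplitudes sampled on a fixed direction set
that fall below ``tau`` times the mean amplitude of the initial low-order
fit are driven towards zero.  This super-resolves the FOD beyond what the
measurement count alone supports and is what buys the narrow-crossing
(down to ~30 degrees) angular resolution.

All signals entering the fit are normalised to the voxel's mean b=0 signal,
so response and FOD amplitudes are dimensionless.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

from .phantom import DWIVolume
from .sphere import (
    cart_to_polar,
    n_sh_coeffs,
    sh_basis,
    sh_degrees,
    sphere_points,
    zonal_expand,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ResponseFunction",
    "FODField",
    "estimate_response",
    "tensor_response",
    "CSDFitter",
    "fit_csd",
    "fit_fod_field",
    "find_fod_peaks",
]

#: direction-set sizes: soft-constraint grid and peak-search/sampling grid
N_CONSTRAINT_DIRS = 300
N_PEAK_DIRS = 724


@dataclass
class ResponseFunction:
    """Axially symmetric single-fibre signal profile (zonal SH coefficients).

    ``zonal[k]`` is the coefficient of Y_{2k,0}; amplitudes are in units of
    S/S0.
    """

    zonal: np.ndarray
    lmax: int

    def __post_init__(self):
        self.zonal = np.asarray(self.zonal, dtype=float)
        if self.lmax % 2:
            raise ValueError("lmax must be even")
        if len(self.zonal) != self.lmax // 2 + 1:
            raise ValueError("zonal coefficient count must be lmax/2 + 1")
        if self.zonal[0] <= 0:
            raise ValueError("l = 0 response coefficient must be positive")

    def convolution_factors(self, lmax: int) -> np.ndarray:
        """Per-coefficient forward factors k_l for an FOD of order ``lmax``."""
        if lmax > self.lmax:
            raise ValueError("response lmax too small for requested FOD lmax")
        ls = sh_degrees(lmax)
        r_l = self.zonal[ls // 2]
        return np.sqrt(4.0 * np.pi / (2.0 * ls + 1.0)) * r_l

    def amplitude(self, cos_theta: np.ndarray) -> np.ndarray:
        """Evaluate the response at polar angle(s) from the fibre axis."""
        ct = np.atleast_1d(np.asarray(cos_theta, dtype=float))
        st = np.sqrt(np.clip(1.0 - ct**2, 0.0, None))
        dirs = np.stack([st, np.zeros_like(ct), ct], axis=1)
        coeffs = zonal_expand(self.zonal, self.lmax)
        return sh_basis(self.lmax, dirs) @ coeffs


@dataclass
class FODField:
    """Per-voxel even-order SH coefficients of the FOD, plus a validity mask."""

    coefficients: np.ndarray  # (X, Y, Z, R)
    lmax: int
    mask: np.ndarray  # (X, Y, Z) bool
    affine: np.ndarray  # 4x4 voxel-to-mm

    def __post_init__(self):
        if self.coefficients.shape[-1] != n_sh_coeffs(self.lmax):
            raise ValueError("coefficient vector length inconsistent with lmax")


def _rotation_to_z(axis: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping ``axis`` onto +z (Rodrigues)."""
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(a, z)
    c = float(a @ z)
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def _zonal_design(lmax: int, dirs: np.ndarray) -> np.ndarray:
    """Design matrix of the m = 0 harmonics only, evaluated at ``dirs``."""
    basis = sh_basis(lmax, dirs)
    cols = []
    i = 0
    for l in range(0, lmax + 1, 2):
        cols.append(basis[:, i + l])
        i += 2 * l + 1
    return np.stack(cols, axis=1)


def estimate_response(
    dwi: DWIVolume,
    single_fibre_mask: np.ndarray,
    axis: np.ndarray,
    lmax: int = 8,
) -> ResponseFunction:
    """Estimate the single-fibre response from coherent voxels.

    The signals of the masked voxels (assumed to contain one fibre
    population along ``axis``) are normalised to their mean b = 0 signal
    and averaged; the gradient directions are rotated so the fibre axis maps
    to +z and the mean signal is projected onto the zonal even harmonics by
    least squares.
    """
    if not np.any(single_fibre_mask):
        raise ValueError("no single-fibre voxels")
    gt = dwi.gradients
    weighted = gt.b_weighted
    sig = dwi.signal[single_fibre_mask]  # (n_vox, G)
    b0 = sig[:, ~weighted].mean(axis=1)
    if np.any(b0 <= 0):
        raise ValueError("non-positive b0 signal in response mask")
    mean_sig = (sig[:, weighted] / b0[:, None]).mean(axis=0)
    rot = _rotation_to_z(axis)
    dirs_rot = gt.directions[weighted] @ rot.T
    design = _zonal_design(lmax, dirs_rot)
    zonal, *_ = np.linalg.lstsq(design, mean_sig, rcond=None)
    return ResponseFunction(zonal=zonal, lmax=lmax)


def tensor_response(
    b_value: float,
    lambda_parallel: float = 1.7e-3,
    lambda_perp: float = 3e-4,
    lmax: int = 8,
    n_quad: int = 128,
) -> ResponseFunction:
    """Analytic response of an axially symmetric tensor, by quadrature.

    r_l = 2 pi * Int_{-1}^{1} exp(-b (l_perp + (l_par - l_perp) t^2))
          * sqrt((2l+1)/4pi) P_l(t) dt
    """
    t, w = np.polynomial.legendre.leggauss(n_quad)
    sig = np.exp(-b_value * (lambda_perp + (lambda_parallel - lambda_perp) * t**2))
    zonal = []
    for l in range(0, lmax + 1, 2):
        pl = np.polynomial.legendre.Legendre.basis(l)(t)
        ylm0 = np.sqrt((2 * l + 1) / (4.0 * np.pi)) * pl
        zonal.append(2.0 * np.pi * float(np.sum(w * sig * ylm0)))
    return ResponseFunction(zonal=np.asarray(zonal), lmax=lmax)


@lru_cache(maxsize=8)
def _peak_basis(lmax: int, n_dirs: int = N_PEAK_DIRS):
    dirs = sphere_points(n_dirs)
    return dirs, sh_basis(lmax, dirs)


class CSDFitter:
    """Precomputed CSD operator for one gradient scheme and response.

    Parameters follow the standard constrained-deconvolution defaults:
    ``lmax`` 8, soft-constraint threshold ``tau`` 0.1 (relative to the mean
    amplitude of the initial low-order fit), 300 constraint directions, 50
    constraint iterations.

    ``lambda_reg`` sets the constraint weight relative to the forward
    operator's norm.  The default ``"auto"`` scales it with the estimated
    per-voxel measurement noise (RMS residual of the unconstrained fit,
    clamped to [0.01, 1]): on noise-free signal the fit stays
    data-dominant, preserving the band-limit's full angular resolution
    (crossings down to 30 degrees at lmax 8) and sub-1e-3 reconvolution
    residuals; at realistic SNR the constraint takes over and suppresses
    the high-order noise amplification inherent to deconvolution by a
    smooth kernel.  A band-limited FOD cannot be made exactly non-negative
    without sacrificing the moments the signal pins down, so residual
    negative side-lobes of order 10% of the peak remain in the
    data-dominant regime; every consumer of FOD amplitudes (tracking, peak
    extraction) clips at zero.
    """

    #: auto constraint weight: lambda_reg = clamp(NOISE_GAIN * sigma_hat)
    NOISE_GAIN = 30.0
    LAMBDA_MIN = 0.01
    LAMBDA_MAX = 1.0

    def __init__(
        self,
        gradients,
        response: ResponseFunction,
        lmax: int = 8,
        n_constraint_dirs: int = N_CONSTRAINT_DIRS,
        tau: float = 0.1,
        max_iter: int = 50,
        lambda_reg: float | str = "auto",
        lmax_init: int = 4,
    ):
        weighted = gradients.b_weighted
        dirs = np.asarray(gradients.directions)[weighted]
        self.weighted = weighted
        self.lmax = lmax
        self.tau = tau
        self.max_iter = max_iter
        n_coef = n_sh_coeffs(lmax)
        if dirs.shape[0] < n_coef:
            logger.info(
                "gradient count %d below coefficient count %d; "
                "super-resolved fit relies on the non-negativity constraint",
                dirs.shape[0],
                n_coef,
            )
        k = response.convolution_factors(lmax)
        ls = sh_degrees(lmax)
        bad = np.abs(k) < 1e-10 * np.abs(k[0])
        if np.any(bad):
            raise ValueError(
                "response has no power at order "
                f"{int(ls[bad][0])}; reduce lmax"
            )
        self.forward = sh_basis(lmax, dirs) * k[None, :]  # (G, R)
        con_dirs = sphere_points(n_constraint_dirs)
        self.b_con = sh_basis(lmax, con_dirs)  # (C, R)
        # initial fit restricted to low orders (well-conditioned)
        self.init_cols = ls <= lmax_init
        f_init = self.forward[:, self.init_cols]
        self.init_solver = np.linalg.pinv(f_init)
        self.full_solver = np.linalg.pinv(self.forward)
        self.fTf = self.forward.T @ self.forward
        self.fT = self.forward.T
        # constraint weight scale: lambda_reg = 1 balances the data term
        self._scale2 = (
            np.linalg.norm(self.forward) / np.linalg.norm(self.b_con)
        ) ** 2
        self.lambda_reg = lambda_reg

    def _lambda2(self, s: np.ndarray) -> float:
        """Constraint weight for one voxel's signal."""
        if self.lambda_reg == "auto":
            resid = s - self.forward @ (self.full_solver @ s)
            sigma = float(np.sqrt(np.mean(resid**2)))
            reg = min(self.LAMBDA_MAX, max(self.LAMBDA_MIN, self.NOISE_GAIN * sigma))
        else:
            reg = float(self.lambda_reg)
        return reg**2 * self._scale2

    def fit(self, signal: np.ndarray) -> np.ndarray:
        """Deconvolve one voxel's b>0 signal (already S0-normalised)."""
        s = np.asarray(signal, dtype=float)
        lam2 = self._lambda2(s)
        f = np.zeros(self.forward.shape[1])
        f[self.init_cols] = self.init_solver @ s
        amp0 = self.b_con @ f
        threshold = self.tau * float(amp0.mean())
        rhs = self.fT @ s
        prev_neg = None
        for _ in range(self.max_iter):
            amp = self.b_con @ f
            neg = amp < threshold
            if prev_neg is not None and np.array_equal(neg, prev_neg):
                break
            prev_neg = neg
            b_neg = self.b_con[neg]
            lhs = self.fTf + lam2 * (b_neg.T @ b_neg)
            try:
                f = cho_solve(cho_factor(lhs), rhs)
            except np.linalg.LinAlgError:  # pragma: no cover
                f = np.linalg.lstsq(lhs, rhs, rcond=None)[0]
        return f

    def predict(self, coeffs: np.ndarray) -> np.ndarray:
        """Reconvolve FOD coefficients back to the measured signal."""
        return self.forward @ coeffs


def fit_csd(
    signal: np.ndarray,
    gradients,
    response: ResponseFunction,
    lmax: int = 8,
    n_constraint_dirs: int = N_CONSTRAINT_DIRS,
    tau: float = 0.1,
    max_iter: int = 50,
    lambda_reg: float | str = "auto",
) -> np.ndarray:
    """One-voxel convenience wrapper around :class:`CSDFitter`.

    ``signal`` covers the full gradient table; b = 0 entries are used for
    normalisation.
    """
    fitter = CSDFitter(
        gradients,
        response,
        lmax=lmax,
        n_constraint_dirs=n_constraint_dirs,
        tau=tau,
        max_iter=max_iter,
        lambda_reg=lambda_reg,
    )
    s = np.asarray(signal, dtype=float)
    b0 = s[~fitter.weighted].mean()
    return fitter.fit(s[fitter.weighted] / b0)


def fit_fod_field(
    dwi: DWIVolume,
    response: ResponseFunction,
    lmax: int = 8,
    tau: float = 0.1,
    max_iter: int = 50,
    lambda_reg: float | str = "auto",
) -> FODField:
    """Fit CSD in every brain-mask voxel of a DWI volume."""
    fitter = CSDFitter(dwi.gradients, response, lmax=lmax, tau=tau,
                       max_iter=max_iter, lambda_reg=lambda_reg)
    weighted = fitter.weighted
    shape = dwi.signal.shape[:3]
    coeffs = np.zeros(shape + (n_sh_coeffs(lmax),))
    mask = dwi.brain_mask.copy()
    idx = np.argwhere(mask)
    n_failed = 0
    for i, j, k in idx:
        sig = dwi.signal[i, j, k]
        b0 = sig[~weighted].mean()
        if b0 <= 0:
            mask[i, j, k] = False
            n_failed += 1
            continue
        coeffs[i, j, k] = fitter.fit(sig[weighted] / b0)
    if n_failed:
        logger.warning("CSD fit excluded %d voxels", n_failed)
    return FODField(coefficients=coeffs, lmax=lmax, mask=mask, affine=dwi.affine)


def _infer_lmax(n_coef: int) -> int:
    lmax = int(round((-3 + np.sqrt(1 + 8 * n_coef)) / 2))
    if n_sh_coeffs(lmax) != n_coef:
        raise ValueError(f"no even lmax matches {n_coef} coefficients")
    return lmax


def find_fod_peaks(
    coefficients: np.ndarray,
    min_separation_deg: float = 15.0,
    rel_threshold: float = 0.25,
) -> tuple[np.ndarray, np.ndarray]:
    """Extract FOD peak orientations and amplitudes.

    Local maxima of the FOD amplitude over a 724-point sphere grid are
    refined by continuous maximisation on the sphere; peaks below
    ``rel_threshold`` x the largest amplitude, or within
    ``min_separation_deg`` of a stronger peak (antipodes identified), are
    discarded.  Returns ``(directions (n, 3), amplitudes (n,))`` sorted by
    amplitude, strongest first.
    """
    coeffs = np.asarray(coefficients, dtype=float)
    if not np.any(coeffs):
        return np.zeros((0, 3)), np.zeros(0)
    lmax = _infer_lmax(len(coeffs))
    dirs, basis = _peak_basis(lmax)
    amp = basis @ coeffs
    # grid-local maxima within an angular neighbourhood (antipodal metric)
    cos_nb = np.cos(np.radians(12.0))
    adot = np.abs(dirs @ dirs.T)
    cand = []
    for i in np.argsort(amp)[::-1][:200]:
        if amp[i] <= 0:
            break
        nb = adot[i] >= cos_nb
        if amp[i] >= amp[nb].max():
            cand.append(i)

    def neg_amp(tp):
        st = np.sin(tp[0])
        d = np.array([st * np.cos(tp[1]), st * np.sin(tp[1]), np.cos(tp[0])])
        return -float(sh_basis(lmax, d[None, :])[0] @ coeffs)

    refined = []
    for i in cand:
        theta, phi = cart_to_polar(dirs[i][None, :])
        res = minimize(
            neg_amp,
            np.array([theta[0], phi[0]]),
            method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-10, "maxiter": 200},
        )
        t, p = res.x
        d = np.array(
            [np.sin(t) * np.cos(p), np.sin(t) * np.sin(p), np.cos(t)]
        )
        if d[2] < 0:
            d = -d
        refined.append((d, -res.fun))
    refined.sort(key=lambda x: -x[1])
    kept_dirs: list[np.ndarray] = []
    kept_amp: list[float] = []
    cos_sep = np.cos(np.radians(min_separation_deg))
    for d, a in refined:
        if a <= 0:
            continue
        if kept_amp and a < rel_threshold * kept_amp[0]:
            continue
        if any(abs(float(d @ kd)) >= cos_sep for kd in kept_dirs):
            continue
        kept_dirs.append(d)
        kept_amp.append(a)
    if not kept_dirs:
        return np.zeros((0, 3)), np.zeros(0)
    return np.stack(kept_dirs), np.asarray(kept_amp)


def angular_resolution_sweep(
    b_value: float = 3000.0,
    n_directions: int = 300,
    angles_deg=tuple(range(90, 15, -5)),
    lmax: int = 8,
    lambda_parallel: float = 1.7e-3,
    lambda_perp: float = 3e-4,
    peak_tolerance_deg: float = 10.0,
    scheme_seed: int = 0,
) -> tuple[float, dict[int, int]]:
    """Smallest noise-free crossing angle resolved into two correct peaks.

    Simulates the noise-free two-tensor signal of two equal-weight fibre
    populations crossing at each swept angle on a dense single-shell
    scheme, deconvolves with the matched (analytic tensor) response, and
    counts FOD peaks.  An angle is "resolved" when exactly two peaks are
    found, each within ``peak_tolerance_deg`` of a true fibre orientation.
    Returns the smallest resolved angle (inf if none) and the per-angle
    peak counts.
    """
    from .phantom import make_gradient_scheme

    gt = make_gradient_scheme(n_directions, b_value, seed=scheme_seed)
    response = tensor_response(
        b_value, lambda_parallel, lambda_perp, lmax=lmax
    )
    fitter = CSDFitter(gt, response, lmax=lmax)
    dirs = gt.directions[gt.b_weighted]
    dl = lambda_parallel - lambda_perp
    u1 = np.array([0.0, 0.0, 1.0])
    smallest = np.inf
    peak_counts: dict[int, int] = {}
    for ang in sorted(angles_deg, reverse=True):
        a = np.radians(ang)
        u2 = np.array([np.sin(a), 0.0, np.cos(a)])
        sig = 0.5 * np.exp(
            -b_value * (lambda_perp + dl * (dirs @ u1) ** 2)
        ) + 0.5 * np.exp(-b_value * (lambda_perp + dl * (dirs @ u2) ** 2))
        peaks, _ = find_fod_peaks(fitter.fit(sig))
        peak_counts[int(ang)] = len(peaks)
        if len(peaks) != 2:
            continue
        errs = []
        for u in (u1, u2):
            cosang = np.clip(np.abs(peaks @ u), 0.0, 1.0)
            errs.append(np.degrees(np.arccos(cosang.max())))
        if max(errs) <= peak_tolerance_deg:
            smallest = float(ang)
    return smallest, peak_counts
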
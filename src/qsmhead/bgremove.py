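"""Background field removal inside an ROI.

Field contributions from susceptibility sources *outside* an ROI are
harmonic inside it.  Each method here exploits that in a different way:

* SMV / RESHARP / VSHARP — the spherical mean value property: a harmonic
  function equals its mean over any interior ball, so subtracting the
  spherical mean annihilates the background (SHARP family).  RESHARP adds
  a Tikhonov-regularized deconvolution on the eroded mask; VSHARP uses a
  variable kernel radius that shrinks toward the boundary to limit
  erosion, then deconvolves the smallest kernel.
* PDF — projection onto dipole fields: fits susceptibility sources
  supported strictly outside the ROI whose induced field best matches the
  measured field inside, and subtracts their field.
* LBV — solves the Laplace boundary-value problem on the (peeled) ROI with
  the total field as boundary data; the harmonic solution is the
  background.

All methods erode the usable support; the erosion-sweep benchmark
quantifies the accuracy/erosion trade-off, including on a tumor placed at
the ROI boundary, and :func:`mask_pre_dilation` implements the one-voxel
a-priori expansion that protects boundary tumor voxels from erosion.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import fft as sp_fft
from scipy import ndimage, sparse
from scipy.sparse.linalg import LinearOperator, cg, spsolve

from .forward import DipoleKernel, FieldVolume, dipole_kernel

__all__ = [
    "BgRemovalResult",
    "smv_filter",
    "resharp",
    "vsharp",
    "pdf",
    "lbv",
    "residual_field_correction",
    "erosion_sweep",
    "mask_pre_dilation",
]

_STRUCT6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class BgRemovalResult:
    """Local field plus the support actually usable after erosion."""

    local_field: FieldVolume
    effective_mask: np.ndarray
    method: str
    params: dict = dc_field(default_factory=dict)
    erosion_fraction_roi: float | None = None
    erosion_fraction_gtv: float | None = None

    def with_erosion_stats(self, roi_mask: np.ndarray,
                           gtv_mask: np.ndarray | None = None) -> "BgRemovalResult":
        roi_mask = np.asarray(roi_mask, dtype=bool)
        kept = (self.effective_mask & roi_mask).sum()
        self.erosion_fraction_roi = 100.0 * (1.0 - kept / max(roi_mask.sum(), 1))
        if gtv_mask is not None:
            gtv_mask = np.asarray(gtv_mask, dtype=bool)
            kept_g = (self.effective_mask & gtv_mask).sum()
            self.erosion_fraction_gtv = 100.0 * (1.0 - kept_g / max(gtv_mask.sum(), 1))
        return self


def _field_values(f) -> tuple[np.ndarray, FieldVolume | None]:
    if isinstance(f, FieldVolume):
        return f.values, f
    return np.asarray(f, dtype=float), None


def _wrap_like(values: np.ndarray, template: FieldVolume | None) -> FieldVolume:
    if template is None:
        return FieldVolume(values, unit="Hz")
    return FieldVolume(values, unit=template.unit, B0=template.B0,
                       gamma=template.gamma)


def _ball_offsets(radius: int) -> np.ndarray:
    r = int(radius)
    g = np.mgrid[-r:r + 1, -r:r + 1, -r:r + 1]
    return (g[0] ** 2 + g[1] ** 2 + g[2] ** 2) <= r**2


def _ball_kernel_fft(shape, radius: int) -> np.ndarray:
    """FFT of the normalized rasterized ball, centered at the origin sample."""
    ball = _ball_offsets(radius).astype(float)
    ball /= ball.sum()
    k = np.zeros(shape)
    r = radius
    idx = [np.arange(-r, r + 1) % n for n in shape]
    k[np.ix_(*idx)] = ball
    return sp_fft.fftn(k, workers=-1)


def _smv(vol: np.ndarray, radius: int, kfft: np.ndarray | None = None,
         pad: int | None = None):
    """Spherical mean of ``vol`` over radius-r balls (zero-padded convolution)."""
    r = int(radius)
    p = r if pad is None else pad
    padded = np.pad(vol.astype(float), p)
    if kfft is None:
        kfft = _ball_kernel_fft(padded.shape, r)
    out = sp_fft.ifftn(sp_fft.fftn(padded, workers=-1) * kfft, workers=-1).real
    sl = tuple(slice(p, p + s) for s in vol.shape)
    return out[sl]


def _mask_extent(mask: np.ndarray) -> int:
    idx = np.where(mask)
    return min(int(i.max() - i.min() + 1) for i in idx)


def smv_filter(field, mask: np.ndarray, radius: int):
    """Subtract the spherical mean over radius-r balls (SHARP high-pass).

    Returns ``(filtered_field, eroded_mask)``; the eroded mask keeps only
    voxels whose ball lies entirely inside the input mask, where the
    spherical mean is trustworthy.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    if 2 * radius > _mask_extent(mask):
        raise ValueError("kernel radius exceeds half the ROI extent")
    vals, tmpl = _field_values(field)
    p = int(radius)
    padded_shape = tuple(s + 2 * p for s in vals.shape)
    kfft = _ball_kernel_fft(padded_shape, int(radius))
    sm = _smv(vals * mask, radius, kfft=kfft)
    cover = _smv(mask.astype(float), radius, kfft=kfft)
    eroded = cover >= 1.0 - 1e-6
    filtered = np.where(eroded, vals - sm, 0.0)
    return _wrap_like(filtered, tmpl), eroded


def resharp(field, mask: np.ndarray, radius: int = 4, tik_lambda: float = 1e-4,
            tol: float = 1e-6, max_iter: int = 1000) -> BgRemovalResult:
    """SMV filtering + Tikhonov-regularized deconvolution on the eroded mask.

    Solves ``min_x ||M (S x - S f)||^2 + lambda ||x||^2`` with
    ``S = I - SMV_r`` restricted to the eroded mask, by conjugate
    gradients on the normal equations (zero initialization).
    """
    if tik_lambda <= 0:
        raise ValueError("tik_lambda must be positive")
    vals, tmpl = _field_values(field)
    mask = np.asarray(mask, dtype=bool)
    p = int(radius)
    padded_shape = tuple(s + 2 * p for s in vals.shape)
    kfft = _ball_kernel_fft(padded_shape, int(radius))

    cover = _smv(mask.astype(float), radius, kfft=kfft)
    eroded = cover >= 1.0 - 1e-6
    m = eroded.astype(float)

    def S(v):
        return v - _smv(v, radius, kfft=kfft)

    b = m * S(vals * mask)
    rhs = (m * S(b)).ravel()  # S^T M S f with S symmetric

    n = vals.size

    def matvec(x):
        v = x.reshape(vals.shape) * m
        out = m * S(m * S(v)) + tik_lambda * v
        return out.ravel()

    A = LinearOperator((n, n), matvec=matvec, dtype=float)
    x, info = cg(A, rhs, rtol=tol, maxiter=max_iter, x0=np.zeros(n))
    if info > 0:
        res = np.linalg.norm(matvec(x) - rhs) / max(np.linalg.norm(rhs), 1e-30)
        raise RuntimeError(f"RESHARP CG did not converge (rel residual {res:.2e})")
    local = x.reshape(vals.shape) * eroded
    return BgRemovalResult(_wrap_like(local, tmpl), eroded, "resharp",
                           {"radius": radius, "tik_lambda": tik_lambda}
                           ).with_erosion_stats(mask)


def vsharp(field, mask: np.ndarray, r_min: int = 1, r_max: int = 10,
           deconv_threshold: float = 0.05) -> BgRemovalResult:
    """Variable-radius SMV: large kernels deep in the ROI, small at the edge.

    Each voxel is filtered with the largest admissible radius (descending
    from ``r_max`` to ``r_min``); each radius's high-pass output is
    deconvolved with its own kernel via a thresholded spectral inverse and
    the per-voxel composite assembled.  The effective mask is the ROI
    eroded by ``r_min``.
    """
    if not (1 <= r_min <= r_max):
        raise ValueError("need 1 <= r_min <= r_max")
    vals, tmpl = _field_values(field)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    if 2 * r_min > _mask_extent(mask):
        raise ValueError("kernel radius exceeds half the ROI extent")

    local = np.zeros_like(vals)
    assigned = np.zeros(vals.shape, dtype=bool)
    eroded_min = None
    masked_vals = vals * mask
    for r in range(int(r_max), int(r_min) - 1, -1):
        if 2 * r > _mask_extent(mask):
            continue
        p = r
        padded_shape = tuple(s + 2 * p for s in vals.shape)
        kfft = _ball_kernel_fft(padded_shape, r)
        cover = _smv(mask.astype(float), r, kfft=kfft)
        er = cover >= 1.0 - 1e-6
        filtered = (masked_vals - _smv(masked_vals, r, kfft=kfft)) * er
        # deconvolve THIS radius's high-pass operator H_r = 1 - ball_fft(r)
        # with a thresholded spectral inverse, then keep only the voxels
        # whose assigned (largest admissible) radius is r
        H = 1.0 - _ball_kernel_fft(vals.shape, r)
        invertible = np.abs(H) > deconv_threshold
        Hinv = np.where(invertible, 1.0 / np.where(invertible, H, 1.0), 0.0)
        deconv = sp_fft.ifftn(sp_fft.fftn(filtered, workers=-1) * Hinv,
                              workers=-1).real
        new = er & ~assigned
        local[new] = deconv[new]
        assigned |= er
        if r == int(r_min):
            eroded_min = er
    if eroded_min is None:
        raise ValueError("no admissible kernel radius for this mask")
    local = np.where(eroded_min, local, 0.0)
    return BgRemovalResult(_wrap_like(local, tmpl), eroded_min, "vsharp",
                           {"r_min": r_min, "r_max": r_max,
                            "deconv_threshold": deconv_threshold}
                           ).with_erosion_stats(mask)


def pdf(field, mask: np.ndarray, pre_erosion: int = 0,
        kernel: DipoleKernel | None = None, voxel_size=(1.0, 1.0, 1.0),
        b0_dir=(0.0, 0.0, 1.0), tol: float = 1e-2,
        max_iter: int = 300) -> BgRemovalResult:
    """Projection onto dipole fields.

    Fits a susceptibility distribution supported strictly outside the
    (optionally pre-eroded) mask whose dipole field best matches the total
    field inside it — conjugate gradients on the normal equations, zero
    initialization, ``tol`` on the relative normal-equation residual —
    and subtracts that fitted background field.
    """
    if pre_erosion < 0:
        raise ValueError("pre_erosion must be >= 0")
    vals, tmpl = _field_values(field)
    mask = np.asarray(mask, dtype=bool)
    m = ndimage.binary_erosion(mask, _STRUCT6, iterations=pre_erosion) \
        if pre_erosion > 0 else mask
    if not m.any():
        raise ValueError("mask empty after pre-erosion")
    if kernel is None:
        kernel = dipole_kernel(vals.shape, voxel_size, b0_dir)
    dk = kernel.dk
    if dk.shape != vals.shape:
        raise ValueError("PDF requires a kernel on the data grid")

    inside = np.where(m.ravel())[0]
    outside = np.where(~m.ravel())[0]

    def conv(v):
        return sp_fft.ifftn(sp_fft.fftn(v, workers=-1) * dk, workers=-1).real

    def matvec(x):
        full = np.zeros(vals.size)
        full[outside] = x
        return conv(full.reshape(vals.shape)).ravel()[inside]

    def rmatvec(y):
        full = np.zeros(vals.size)
        full[inside] = y
        return conv(full.reshape(vals.shape)).ravel()[outside]

    b = vals.ravel()[inside]
    atb = rmatvec(b)

    def normal_matvec(x):
        return rmatvec(matvec(x))

    N = LinearOperator((outside.size, outside.size), matvec=normal_matvec,
                       dtype=float)
    x, info = cg(N, atb, rtol=tol, maxiter=max_iter,
                 x0=np.zeros(outside.size))
    if info > 0:
        res = np.linalg.norm(normal_matvec(x) - atb) / max(np.linalg.norm(atb), 1e-30)
        raise RuntimeError(f"PDF CG did not converge (rel residual {res:.2e})")
    chi_bg = np.zeros(vals.size)
    chi_bg[outside] = x
    background = conv(chi_bg.reshape(vals.shape))
    local = np.where(m, vals - background, 0.0)
    return BgRemovalResult(_wrap_like(local, tmpl), m, "pdf",
                           {"pre_erosion": pre_erosion}
                           ).with_erosion_stats(mask)


def _lbv_solve(vals: np.ndarray, m: np.ndarray, voxel_size, tol, max_iter,
               x0: np.ndarray | None = None):
    """Solve Laplace(u)=0 on the interior of m with u = field on the boundary."""
    interior = ndimage.binary_erosion(m, _STRUCT6)
    boundary = m & ~interior
    n_int = int(interior.sum())
    if n_int == 0:
        return np.where(m, vals, 0.0), interior
    shape = vals.shape
    strides = (shape[1] * shape[2], shape[2], 1)
    flat_int = np.where(interior.ravel())[0]
    idx_map = np.full(vals.size, -1, dtype=np.int64)
    idx_map[flat_int] = np.arange(n_int)
    h2 = [1.0 / v**2 for v in voxel_size]

    rows, cols, data = [], [], []
    rhs = np.zeros(n_int)
    diag = np.zeros(n_int)
    fvals = vals.ravel()
    int_flag = interior.ravel()
    for ax in range(3):
        w = h2[ax]
        for sgn in (+1, -1):
            nb = flat_int + sgn * strides[ax]
            diag -= w
            is_unknown = int_flag[nb]
            rows.append(np.arange(n_int)[is_unknown])
            cols.append(idx_map[nb[is_unknown]])
            data.append(np.full(int(is_unknown.sum()), w))
            known = ~is_unknown
            rhs[known] -= w * fvals[nb[known]]
    rows.append(np.arange(n_int))
    cols.append(np.arange(n_int))
    data.append(diag)
    A = sparse.csr_matrix((np.concatenate(data),
                           (np.concatenate(rows), np.concatenate(cols))),
                          shape=(n_int, n_int))
    if n_int < 4000:
        u = spsolve(A.tocsc(), rhs)
        info = 0
    else:
        x0v = None if x0 is None else x0.ravel()[flat_int]
        u, info = cg(A, rhs, rtol=tol, maxiter=max_iter, x0=x0v)
    if info > 0:
        raise RuntimeError("LBV solver did not converge")
    bg = np.where(m, vals, 0.0)
    bg.ravel()[flat_int] = u
    return bg, interior


def lbv(field, mask: np.ndarray, peel: int = 1, depth: int = 3,
        voxel_size=(1.0, 1.0, 1.0), tol: float = 1e-6,
        max_iter: int = 1000) -> BgRemovalResult:
    """Laplacian boundary value background removal.

    Peels ``peel`` voxel layers off the mask, then solves the Laplace
    equation on the peeled interior with the total field as Dirichlet
    boundary data (7-point finite differences, conjugate gradients).
    ``depth`` controls the grid-coarsening levels used to build the
    solver's initial guess: the same boundary-value problem is first
    solved on a grid downsampled by 2**depth and prolonged back.
    """
    if peel < 1:
        raise ValueError("peel must be >= 1")
    vals, tmpl = _field_values(field)
    mask = np.asarray(mask, dtype=bool)
    m = ndimage.binary_erosion(mask, _STRUCT6, iterations=peel)
    if not m.any():
        raise ValueError("mask empty after peeling")

    x0 = None
    if depth > 0:
        factor = 2 ** int(depth)
        coarse_shape = tuple(max(8, s // factor) for s in vals.shape)
        if all(c < s for c, s in zip(coarse_shape, vals.shape)):
            zoom = [c / s for c, s in zip(coarse_shape, vals.shape)]
            cm = ndimage.zoom(m.astype(float), zoom, order=0) > 0.5
            cv = ndimage.zoom(vals, zoom, order=1)
            if cm.any() and ndimage.binary_erosion(cm, _STRUCT6).any():
                cbg, _ = _lbv_solve(cv, cm, voxel_size, tol, max_iter)
                x0 = ndimage.zoom(cbg, [s / c for c, s in zip(coarse_shape, vals.shape)],
                                  order=1)
                x0 = x0[tuple(slice(0, s) for s in vals.shape)]
                if x0.shape != vals.shape:
                    x0 = None

    background, interior = _lbv_solve(vals, m, voxel_size, tol, max_iter, x0=x0)
    local = np.where(interior, vals - background, 0.0)
    return BgRemovalResult(_wrap_like(local, tmpl), interior, "lbv",
                           {"peel": peel, "depth": depth}
                           ).with_erosion_stats(mask)


def _real_sph_basis(x, y, z, order: int) -> list[np.ndarray]:
    """Real solid harmonics r^l * Y_lm, l <= order, on given coordinates."""
    from scipy.special import sph_harm_y
    r = np.sqrt(x**2 + y**2 + z**2)
    theta = np.arccos(np.where(r > 0, np.clip(z / np.where(r > 0, r, 1.0), -1, 1), 1.0))
    phi = np.arctan2(y, x)
    cols = []
    for l in range(order + 1):
        rl = r**l
        for mdeg in range(-l, l + 1):
            Y = sph_harm_y(l, abs(mdeg), theta, phi)
            if mdeg == 0:
                col = Y.real
            elif mdeg > 0:
                col = np.sqrt(2.0) * (-1.0) ** mdeg * Y.real
            else:
                col = np.sqrt(2.0) * (-1.0) ** mdeg * Y.imag
            cols.append(rl * col)
    return cols


def residual_field_correction(field, mask: np.ndarray, basis: str = "polynomial",
                              order: int = 2, full_output: bool = False):
    """Fit and subtract a smooth residual background over the mask.

    ``basis`` is either a full 3D polynomial of total degree ``order`` or
    real solid spherical harmonics up to degree ``order`` (1..4).
    """
    if order not in (1, 2, 3, 4):
        raise ValueError("order must be in 1..4")
    vals, tmpl = _field_values(field)
    mask = np.asarray(mask, dtype=bool)
    idx = np.where(mask)
    if idx[0].size == 0:
        raise ValueError("mask is empty")
    # normalized coordinates over the mask bounding box
    coords = []
    for ax in range(3):
        lo, hi = idx[ax].min(), idx[ax].max()
        span = max(hi - lo, 1)
        coords.append(2.0 * (idx[ax] - lo) / span - 1.0)
    x, y, z = coords

    if basis == "polynomial":
        cols = [x**i * y**j * z**k
                for i in range(order + 1)
                for j in range(order + 1 - i)
                for k in range(order + 1 - i - j)]
    elif basis == "spherical_harmonic":
        cols = _real_sph_basis(x, y, z, order)
    else:
        raise ValueError(f"unknown basis {basis!r}")
    G = np.column_stack(cols)
    if idx[0].size < G.shape[1]:
        raise ValueError("not enough in-mask voxels for the basis size")
    coef, _, rank, _ = np.linalg.lstsq(G, vals[mask], rcond=None)
    if rank < G.shape[1]:
        flat = [ax for ax, c in enumerate("xyz") if np.ptp(coords[ax]) == 0]
        names = ", ".join("xyz"[a] for a in flat) or "unknown"
        raise ValueError(f"rank-deficient design (degenerate axis: {names})")
    fitted = np.zeros_like(vals)
    fitted[mask] = G @ coef
    corrected = np.where(mask, vals - fitted, 0.0)
    out = _wrap_like(corrected, tmpl)
    if full_output:
        return out, {"coefficients": coef, "basis": basis, "order": order}
    return out


_SWEEP_RUNNERS = {
    "resharp": lambda f, m, p, kw: resharp(f, m, radius=int(p), **kw),
    "vsharp": lambda f, m, p, kw: vsharp(f, m, r_min=int(p), **kw),
    "pdf": lambda f, m, p, kw: pdf(f, m, pre_erosion=int(p), **kw),
    "lbv": lambda f, m, p, kw: lbv(f, m, peel=int(p), **kw),
}


def erosion_sweep(method: str, param_grid, truth_local, total_field,
                  masks: dict, correction_order: int = 2,
                  method_kwargs: dict | None = None) -> pd.DataFrame:
    """Accuracy-vs-erosion benchmark for one background-removal method.

    ``masks`` must contain ``roi`` (brain + GTV evaluation region) and may
    contain ``gtv``.  For each sweep value the method runs on the ROI,
    RMSE/MAE against the ground-truth local field are computed on the
    intersection of the effective support with each evaluation mask, and
    erosion percentages are recorded.  RMSE after an additional
    polynomial residual correction is reported alongside.  Failed runs are
    recorded as rows with NaN metrics, not raised.
    """
    from .metrics import error_metrics

    if method not in _SWEEP_RUNNERS:
        raise ValueError(f"unknown method {method!r}")
    truth, _ = _field_values(truth_local)
    roi = np.asarray(masks["roi"], dtype=bool)
    gtv = np.asarray(masks.get("gtv"), dtype=bool) if masks.get("gtv") is not None else None
    kw = dict(method_kwargs or {})
    rows = []
    for p in param_grid:
        row = {"method": method, "param": p}
        try:
            res = _SWEEP_RUNNERS[method](total_field, roi, p, kw)
            res = res.with_erosion_stats(roi, gtv)
            est = res.local_field.values
            eval_roi = res.effective_mask & roi
            em = error_metrics(est, truth, eval_roi)
            row.update(rmse_roi=em["RMSE"], mae_roi=em["MAE"],
                       erosion_roi_pct=res.erosion_fraction_roi,
                       erosion_gtv_pct=res.erosion_fraction_gtv)
            if gtv is not None and (res.effective_mask & gtv).any():
                row["rmse_gtv"] = error_metrics(est, truth,
                                                res.effective_mask & gtv)["RMSE"]
            else:
                row["rmse_gtv"] = np.nan
            try:
                # score in the complement of the polynomial subspace: the
                # same projection is applied to estimate and truth, so the
                # corrected RMSE is insensitive to smooth content of the
                # truth and can never exceed the uncorrected one
                corr_est = residual_field_correction(est, eval_roi,
                                                     order=correction_order)
                corr_truth = residual_field_correction(truth, eval_roi,
                                                       order=correction_order)
                row["rmse_roi_corrected"] = error_metrics(
                    corr_est.values, corr_truth.values, eval_roi)["RMSE"]
            except ValueError:
                row["rmse_roi_corrected"] = np.nan
            row["error"] = ""
        except (RuntimeError, ValueError) as exc:
            row.update(rmse_roi=np.nan, rmse_gtv=np.nan, mae_roi=np.nan,
                       erosion_roi_pct=np.nan, erosion_gtv_pct=np.nan,
                       rmse_roi_corrected=np.nan, error=str(exc))
        rows.append(row)
    return pd.DataFrame(rows)


def mask_pre_dilation(mask: np.ndarray, voxels: int) -> np.ndarray:
    """Dilate a mask by ``voxels`` applications of the unit 6-connected element."""
    if voxels < 0:
        raise ValueError("voxels must be >= 0")
    mask = np.asarray(mask, dtype=bool)
    if voxels == 0:
        return mask.copy()
    return ndimage.binary_dilation(mask, _STRUCT6, iterations=voxels)
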
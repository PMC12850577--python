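"""Regularized dipole inversion of the local field into susceptibility.

Deconvolving the local field by the unit dipole kernel is ill-posed: D(k)
vanishes on the magic-angle cone.  The whole-head least-norm formulation
stabilizes it by minimizing

    || W (Ms C(chi) - Ms dB) ||^2  +  lambda1 TV(chi)  +  lambda2 || W Ms chi ||^2

over chi supported on the soft-tissue mask Ms, where C is the dipole
convolution, dB the local field (ppm), W a magnitude-derived data weight
normalized to unit brain mean, TV the (isotropic) total variation, and the
default weights are lambda1 = 4e-4 and lambda2 = 1e-3.

The solver is a monotone FISTA (MFISTA): gradient steps on the smooth data
+ Tikhonov part with a Lipschitz step bound, a fast-gradient-projection
inner loop for the TV proximal operator, and acceptance of accelerated
iterates only when they decrease the objective — so the objective is
non-increasing across outer iterations by construction.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import fft as sp_fft
from scipy import ndimage

from .forward import DipoleKernel, FieldVolume, padded_kernel_for

__all__ = [
    "InversionConfig",
    "compute_weight_map",
    "threshold_soft_tissue_mask",
    "ln_qsm_invert",
    "qsm_pipeline",
]


@dataclass
class InversionConfig:
    """Tunables of the dipole inversion.

    lambda1 weights total variation (edge-preserving denoising), lambda2
    the Tikhonov term that suppresses the null-space of the dipole kernel.
    """

    lambda1: float = 4e-4
    lambda2: float = 1e-3
    max_iter: int = 250
    tol: float = 1e-3
    tv_flavor: str = "isotropic"
    tv_inner_iter: int = 15

    def __post_init__(self) -> None:
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("regularization weights must be >= 0")
        if self.tv_flavor not in ("isotropic", "anisotropic"):
            raise ValueError("tv_flavor must be isotropic or anisotropic")


def compute_weight_map(magnitude_echo1: np.ndarray, brain_mask: np.ndarray) -> np.ndarray:
    """First-echo magnitude normalized by its mean over the brain mask."""
    mag = np.asarray(magnitude_echo1, dtype=float)
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if not brain_mask.any():
        raise ValueError("brain mask is empty")
    if np.any(mag < 0):
        raise ValueError("magnitude must be non-negative")
    mean = mag[brain_mask].mean()
    if mean == 0:
        raise ValueError("zero mean magnitude over the brain mask")
    return mag / mean


def threshold_soft_tissue_mask(magnitude_echo1: np.ndarray,
                               threshold: float | None = None) -> np.ndarray:
    """Automatic soft-tissue mask from the first-echo magnitude.

    Otsu bimodal threshold (overridable), largest connected component,
    hole filling.  Air and cortical bone carry almost no signal and fall
    below the threshold; internal air cavities survive as holes only if
    they touch the boundary, so genuinely enclosed cavities are excluded
    by masking out sub-threshold voxels after filling.
    """
    from skimage import filters, measure

    mag = np.asarray(magnitude_echo1, dtype=float)
    if np.ptp(mag) == 0:
        raise ValueError("constant magnitude image: no bimodal threshold; "
                         "supply a manual threshold")
    thr = filters.threshold_otsu(mag) if threshold is None else threshold
    fg = mag > thr
    if not fg.any():
        raise ValueError("empty mask; supply a manual threshold")
    lab = measure.label(fg, connectivity=1)
    largest = lab == np.argmax(np.bincount(lab.ravel())[1:]) + 1
    filled = ndimage.binary_fill_holes(largest)
    # fill only small (noise) holes; enclosed low-signal cavities of
    # meaningful size are genuine air/bone and stay excluded
    min_cavity_voxels = 10
    holes = filled & ~largest
    hole_lab, n = ndimage.label(holes)
    out = largest.copy()
    for i in range(1, n + 1):
        sel = hole_lab == i
        if sel.sum() < min_cavity_voxels:
            out |= sel
    return out


def _tv_value(x: np.ndarray, flavor: str) -> float:
    grads = [np.diff(x, axis=ax, append=np.take(x, [-1], axis=ax))
             for ax in range(3)]
    if flavor == "isotropic":
        return float(np.sqrt(sum(g**2 for g in grads)).sum())
    return float(sum(np.abs(g).sum() for g in grads))


def _grad(x: np.ndarray) -> list[np.ndarray]:
    return [np.diff(x, axis=ax, append=np.take(x, [-1], axis=ax))
            for ax in range(3)]


def _div(p: list[np.ndarray]) -> np.ndarray:
    out = np.zeros_like(p[0])
    for ax, g in enumerate(p):
        d = np.diff(g, axis=ax, prepend=np.take(g, [0], axis=ax) * 0)
        # adjoint of forward difference with replicated edge
        out -= d
    return out


def _tv_prox(b: np.ndarray, weight: float, n_iter: int, flavor: str,
             state: dict | None = None) -> np.ndarray:
    """Fast gradient projection for the TV proximal operator (dual ascent).

    ``state`` optionally warm-starts the dual variables from the previous
    outer iteration, which sharpens the inexact prox considerably.
    """
    if weight <= 0:
        return b
    if state is not None and "p" in state:
        p = [pi.copy() for pi in state["p"]]
    else:
        p = [np.zeros_like(b) for _ in range(3)]
    q = [pi.copy() for pi in p]
    t = 1.0
    L = 12.0  # Lipschitz bound of the dual gradient in 3D
    for _ in range(n_iter):
        x = b - weight * _div(q)
        g = _grad(x)
        p_new = [qi + (1.0 / (weight * L)) * gi for qi, gi in zip(q, g)]
        if flavor == "isotropic":
            norm = np.sqrt(sum(pi**2 for pi in p_new))
            scale = 1.0 / np.maximum(1.0, norm)
            p_new = [pi * scale for pi in p_new]
        else:
            p_new = [np.clip(pi, -1.0, 1.0) for pi in p_new]
        t_new = (1.0 + np.sqrt(1.0 + 4.0 * t**2)) / 2.0
        q = [pn + ((t - 1.0) / t_new) * (pn - po) for pn, po in zip(p_new, p)]
        p, t = p_new, t_new
    if state is not None:
        state["p"] = [pi.copy() for pi in p]
    return b - weight * _div(p)


def ln_qsm_invert(local_field, soft_mask: np.ndarray,
                  weight: np.ndarray | None = None,
                  cfg: InversionConfig | None = None,
                  kernel: DipoleKernel | None = None,
                  voxel_size=(1.0, 1.0, 1.0), b0_dir=(0.0, 0.0, 1.0),
                  pad_factor: float = 2.0, full_output: bool = False):
    """TV + Tikhonov regularized dipole inversion (ppm in, ppm out).

    ``local_field`` may be a :class:`FieldVolume` (converted to ppm) or a
    plain ppm array.  chi is constrained to the soft-tissue mask (zero
    outside).  Deterministic: zero initialization, fixed iteration
    schedule.  Raises if the objective stops decreasing for 10 consecutive
    outer iterations before the tolerance is met.
    """
    cfg = cfg or InversionConfig()
    if isinstance(local_field, FieldVolume):
        b = local_field.to_ppm().values
    else:
        b = np.asarray(local_field, dtype=float)
    soft_mask = np.asarray(soft_mask, dtype=bool)
    if weight is None:
        weight = np.ones_like(b)
    W2 = (np.asarray(weight, dtype=float) ** 2) * soft_mask
    b = b * soft_mask
    if kernel is None:
        kernel = padded_kernel_for(b.shape, voxel_size, b0_dir, pad_factor)

    from .forward import field_from_chi

    def C(x):
        return field_from_chi(x, kernel).values

    def objective(x):
        r = C(x) - b
        data = float((W2 * r * r)[soft_mask].sum())
        tik = cfg.lambda2 * float((W2 * x * x)[soft_mask].sum())
        return data + cfg.lambda1 * _tv_value(x, cfg.tv_flavor) + tik

    def grad_smooth(x):
        r = W2 * (C(x) - b)
        return 2.0 * (C(r) + cfg.lambda2 * W2 * x)  # kernel is symmetric

    wmax = float(W2.max()) if W2.max() > 0 else 1.0
    L = 2.0 * wmax * (4.0 / 9.0 + cfg.lambda2)
    step = 1.0 / L

    x = np.zeros_like(b)
    y = x.copy()
    t = 1.0
    F_hist = [objective(x)]
    stall = 0
    prox_state: dict = {}
    for it in range(cfg.max_iter):
        z = y - step * grad_smooth(y)
        z = _tv_prox(z, cfg.lambda1 * step, cfg.tv_inner_iter, cfg.tv_flavor,
                     state=prox_state)
        z *= soft_mask
        Fz = objective(z)
        if Fz > F_hist[-1]:
            if Fz - F_hist[-1] <= 1e-4 * max(abs(F_hist[-1]), 1e-30):
                break  # within inexact-prox tolerance: converged at x
            # monotone safeguard: reject, restart momentum from x
            stall += 1
            if stall >= 10:
                raise RuntimeError(
                    f"inversion diverged: objective increased over 10 "
                    f"consecutive iterations (last F={Fz:.6g} > {F_hist[-1]:.6g})")
            y = x.copy()
            t = 1.0
            F_hist.append(F_hist[-1])
            continue
        stall = 0
        t_new = (1.0 + np.sqrt(1.0 + 4.0 * t**2)) / 2.0
        y = z + ((t - 1.0) / t_new) * (z - x)
        rel = np.linalg.norm(z - x) / max(np.linalg.norm(z), 1e-30)
        x, t = z, t_new
        F_hist.append(Fz)
        if rel < cfg.tol and it > 2:
            break
    chi = x * soft_mask
    if full_output:
        return chi, {"objective": np.array(F_hist), "iterations": len(F_hist) - 1}
    return chi


def _hash(a: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(a).tobytes()).hexdigest()[:16]


def qsm_pipeline(series, masks: dict, cfg: dict | None = None):
    """Full reconstruction chain: unwrap -> field map -> VSHARP ->
    2nd-order polynomial correction -> dipole inversion.

    ``masks`` requires ``soft`` (soft-tissue ROI) and ``brain``; optional
    ``gtv`` (pre-dilated by one voxel before background removal so
    boundary tumor voxels survive erosion) and ``exclude`` (regions of
    extreme susceptibility variation, removed from the ROI).  Returns
    ``(chi, provenance)`` with chi in ppm.
    """
    from .bgremove import (lbv, mask_pre_dilation, pdf, resharp,
                           residual_field_correction, vsharp)
    from .unwrap import temporal_unwrap_and_fieldmap

    cfg = dict(cfg or {})
    method = cfg.get("unwrap_method", "quality_guided")
    bg_method = cfg.get("bg_method", "vsharp")
    r_min = int(cfg.get("vsharp_r_min", 1))
    r_max = int(cfg.get("vsharp_r_max", 10))
    poly_order = int(cfg.get("poly_order", 2))
    inv_cfg = InversionConfig(
        lambda1=float(cfg.get("lambda1", 4e-4)),
        lambda2=float(cfg.get("lambda2", 1e-3)),
        max_iter=int(cfg.get("max_iter", 250)),
        tol=float(cfg.get("tol", 1e-3)),
        tv_flavor=cfg.get("tv_flavor", "isotropic"),
    )
    pad_factor = float(cfg.get("pad_factor", 2.0))

    soft = np.asarray(masks["soft"], dtype=bool)
    brain = np.asarray(masks.get("brain", soft), dtype=bool)
    gtv = masks.get("gtv")
    exclude = masks.get("exclude")

    roi = soft.copy()
    if exclude is not None:
        # excluded structures are pre-dilated by one voxel so their
        # partial-volume rim (extreme field values) leaves the ROI too
        roi &= ~mask_pre_dilation(np.asarray(exclude, dtype=bool), 1)
    if gtv is not None:
        roi |= mask_pre_dilation(np.asarray(gtv, dtype=bool), 1)

    provenance = {"stages": [], "masks": {k: _hash(np.asarray(v))
                                          for k, v in masks.items() if v is not None}}

    def stage(name, **params):
        provenance["stages"].append({"stage": name, **params})

    try:
        field_hz, _ = temporal_unwrap_and_fieldmap(series, roi, method=method)
        stage("unwrap_fieldmap", method=method, n_echoes=series.n_echoes)

        if bg_method == "vsharp":
            bg = vsharp(field_hz, roi, r_min=r_min, r_max=r_max)
        elif bg_method == "lbv":
            bg = lbv(field_hz, roi, peel=int(cfg.get("lbv_peel", 1)),
                     depth=int(cfg.get("lbv_depth", 3)),
                     voxel_size=series.params.voxel_size)
        elif bg_method == "resharp":
            bg = resharp(field_hz, roi, radius=int(cfg.get("resharp_radius", 4)),
                         tik_lambda=float(cfg.get("resharp_lambda", 1e-4)))
        elif bg_method == "pdf":
            bg = pdf(field_hz, roi, pre_erosion=int(cfg.get("pdf_pre_erosion", 1)),
                     voxel_size=series.params.voxel_size,
                     b0_dir=series.params.b0_dir)
        else:
            raise ValueError(f"unknown bg_method {bg_method!r}")
        stage(bg_method, r_min=r_min, r_max=r_max,
              erosion_roi_pct=bg.erosion_fraction_roi)

        corrected = residual_field_correction(bg.local_field,
                                              bg.effective_mask,
                                              basis="polynomial",
                                              order=poly_order)
        stage("residual_correction", basis="polynomial", order=poly_order)

        weight = compute_weight_map(series.magnitude[0], brain)
        field_ppm = corrected.to_ppm().values
        inv_mask = bg.effective_mask & soft
        chi = ln_qsm_invert(field_ppm, inv_mask, weight, inv_cfg,
                            voxel_size=series.params.voxel_size,
                            b0_dir=series.params.b0_dir,
                            pad_factor=pad_factor)
        stage("ln_qsm_invert", lambda1=inv_cfg.lambda1,
              lambda2=inv_cfg.lambda2, max_iter=inv_cfg.max_iter)
    except Exception as exc:
        failed = provenance["stages"][-1]["stage"] if provenance["stages"] else "start"
        raise RuntimeError(f"pipeline failed after stage {failed!r}: {exc}") from exc

    return chi, provenance
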
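"""Evaluation and exclusion geometry: peri-bone shell, exclusion masks.

The peri-bone shell is the evaluation ROI where unwrapping is hardest:
the bone interface dilated with a rasterized spherical kernel,
intersected with brain.  A 13-voxel-diameter kernel (radius 6 voxels) at
0.75 x 0.75 x 2.5 mm voxels reaches 4.5 mm in-plane and 15 mm
through-plane.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = ["peri_bone_shell", "shell_physical_extent", "exclusion_mask"]


def _ball(radius: int) -> np.ndarray:
    g = np.mgrid[-radius:radius + 1, -radius:radius + 1, -radius:radius + 1]
    return (g[0] ** 2 + g[1] ** 2 + g[2] ** 2) <= radius**2


def peri_bone_shell(bone_mask: np.ndarray, kernel_diameter: int,
                    brain_mask: np.ndarray) -> np.ndarray:
    """Shell = (bone dilated by a sphere of given voxel diameter) - bone,
    intersected with brain."""
    if kernel_diameter % 2 == 0 or kernel_diameter < 3:
        raise ValueError("kernel_diameter must be odd and >= 3 "
                         "(a centered sphere needs an odd voxel diameter)")
    bone_mask = np.asarray(bone_mask, dtype=bool)
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if not bone_mask.any():
        return np.zeros_like(bone_mask)
    radius = (kernel_diameter - 1) // 2
    dilated = ndimage.binary_dilation(bone_mask, structure=_ball(radius))
    return dilated & ~bone_mask & brain_mask


def shell_physical_extent(kernel_diameter: int, voxel_size) -> tuple[float, ...]:
    """Physical reach (mm per axis) of the dilation radius."""
    if kernel_diameter % 2 == 0:
        raise ValueError("kernel_diameter must be odd")
    r = (kernel_diameter - 1) / 2.0
    return tuple(float(r * v) for v in voxel_size)


def exclusion_mask(labels: np.ndarray, exclude: list[str], soft_mask: np.ndarray,
                   structure_table: dict[int, tuple[str, float]]) -> np.ndarray:
    """Soft-tissue mask minus the listed structures (each pre-dilated by
    one voxel to catch partial-volume rims)."""
    labels = np.asarray(labels)
    soft_mask = np.asarray(soft_mask, dtype=bool)
    known = {n for n, _ in structure_table.values()}
    unknown = [n for n in exclude if n not in known]
    if unknown:
        raise ValueError(f"unknown structure names: {unknown}")
    out = soft_mask.copy()
    for name in exclude:
        ids = [i for i, (n, _) in structure_table.items() if n == name]
        m = np.isin(labels, ids)
        m = ndimage.binary_dilation(m, _ball(1))
        out &= ~m
    return out
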
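"""NIfTI volume I/O, plain-text configuration, and pipeline orchestration.

Volumes travel as NIfTI-1 with the affine carrying voxel geometry; phase
is stored in radians in (-pi, pi]; field maps carry their unit in the
header description.  Config files are one ``key = value`` per line with
``#`` comments; unknown keys fail with a nearest-match suggestion.
"""

from __future__ import annotations

import difflib
import hashlib
import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["read_volume", "write_volume", "parse_config", "run_config",
           "CONFIG_KEYS"]

log = logging.getLogger("qsmhead")


def read_volume(path):
    """Read a NIfTI volume.  Returns ``(data, affine, voxel_size_mm)``."""
    img = nib.load(str(path))
    affine = img.affine
    if affine is None or not np.all(np.isfinite(affine)):
        raise ValueError(f"{path}: missing or invalid affine")
    data = np.asarray(img.dataobj)
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, affine, voxel_size


def write_volume(data, path, affine=None, voxel_size=None, description: str = ""):
    """Write a NIfTI volume; geometry from ``affine`` or diagonal voxel size."""
    data = np.asarray(data)
    if affine is None:
        vs = voxel_size or (1.0, 1.0, 1.0)
        affine = np.diag(list(vs) + [1.0])
    img = nib.Nifti1Image(data, affine)
    if description:
        img.header["descrip"] = description.encode()[:79]
    nib.save(img, str(path))


#: Recognized pipeline configuration keys with defaults.
CONFIG_KEYS = {
    "grid_shape": "64,64,64",
    "voxel_size": "1,1,1",
    "seed": "0",
    "B0": "3.0",
    "TEs_ms": "4,8,12,16",
    "noise_sd": "0.0",
    "gtv_center": "",
    "gtv_radius_mm": "6.0",
    "gtv_chi": "0.3",
    "unwrap_method": "quality_guided",
    "bg_method": "vsharp",
    "vsharp_r_min": "1",
    "vsharp_r_max": "10",
    "lbv_peel": "1",
    "lbv_depth": "3",
    "resharp_radius": "4",
    "resharp_lambda": "1e-4",
    "pdf_pre_erosion": "1",
    "poly_order": "2",
    "lambda1": "4e-4",
    "lambda2": "1e-3",
    "max_iter": "250",
    "tol": "1e-3",
    "tv_flavor": "isotropic",
    "pad_factor": "2.0",
    "out_dir": "qsmhead_out",
}


def parse_config(path) -> dict[str, str]:
    """Parse a ``key = value`` config file; unknown keys raise with the
    nearest valid key suggested."""
    cfg = dict(CONFIG_KEYS)
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, val = (s.strip() for s in line.split("=", 1))
        if key not in CONFIG_KEYS:
            hint = difflib.get_close_matches(key, CONFIG_KEYS, n=1)
            suffix = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ValueError(f"{path}:{lineno}: unknown key {key!r}{suffix}")
        cfg[key] = val
    return cfg


def _triple(s: str, cast=float):
    return tuple(cast(v) for v in s.split(","))


def _hash_array(a) -> str:
    return hashlib.sha256(np.ascontiguousarray(a).tobytes()).hexdigest()[:16]


def run_config(config, out_dir=None) -> dict:
    """Run the full simulate -> reconstruct -> evaluate chain from a config.

    ``config`` is a path to a ``key = value`` file or an already-parsed
    dict.  Writes phantom labels/chi, echo magnitude/phase, the
    susceptibility map and a metrics + provenance JSON under ``out_dir``;
    returns the provenance record.  Re-running an unchanged config is
    bit-reproducible (fixed seeds, deterministic solvers).
    """
    from . import forward, invert, metrics, phantom

    cfg = dict(CONFIG_KEYS)
    if isinstance(config, (str, Path)):
        cfg.update(parse_config(config))
    else:
        unknown = set(config) - set(CONFIG_KEYS)
        if unknown:
            k = sorted(unknown)[0]
            hint = difflib.get_close_matches(k, CONFIG_KEYS, n=1)
            suffix = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ValueError(f"unknown config key {k!r}{suffix}")
        cfg.update({k: str(v) for k, v in config.items()})

    out = Path(out_dir or cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    grid = _triple(cfg["grid_shape"], int)
    vs = _triple(cfg["voxel_size"])

    log.info("building phantom %s", grid)
    ph = phantom.build_head_phantom(grid, vs, seed=seed)
    if cfg["gtv_center"]:
        center = _triple(cfg["gtv_center"])
    else:
        center = tuple(0.5 * s for s in grid[:2]) + (0.27 * grid[2],)
    ph = phantom.insert_gtv(ph, center, float(cfg["gtv_radius_mm"]),
                            float(cfg["gtv_chi"]))

    params = forward.AcquisitionParams(B0=float(cfg["B0"]),
                                       TEs_ms=_triple(cfg["TEs_ms"]),
                                       voxel_size=vs,
                                       noise_sd=float(cfg["noise_sd"]))
    series, true_phase, field = forward.simulate_multiecho_signal(
        ph.chi, params, seed=seed, labels=ph.labels,
        structure_table=ph.structure_table)

    masks = {"soft": ph.soft_tissue_mask(), "brain": ph.soft_tissue_mask(),
             "gtv": ph.mask("GTV")}
    pipeline_cfg = {k: cfg[k] for k in ("unwrap_method", "bg_method",
                                        "vsharp_r_min", "vsharp_r_max",
                                        "lbv_peel", "lbv_depth",
                                        "resharp_radius", "resharp_lambda",
                                        "pdf_pre_erosion",
                                        "poly_order", "lambda1",
                                        "lambda2", "max_iter", "tol",
                                        "tv_flavor", "pad_factor")}
    chi, provenance = invert.qsm_pipeline(series, masks, pipeline_cfg)

    gtv = ph.mask("GTV")
    em = metrics.error_metrics(chi, ph.chi, gtv & (chi != 0)) \
        if (gtv & (chi != 0)).any() else {"RMSE": None, "MAE": None}

    write_volume(ph.labels.astype(np.int16), out / "labels.nii.gz", voxel_size=vs)
    write_volume(ph.chi, out / "chi_truth.nii.gz", voxel_size=vs,
                 description="chi ppm")
    write_volume(np.moveaxis(series.magnitude, 0, -1), out / "magnitude.nii.gz",
                 voxel_size=vs)
    write_volume(np.moveaxis(series.phase, 0, -1), out / "phase.nii.gz",
                 voxel_size=vs, description="phase rad")
    write_volume(chi, out / "chi_estimate.nii.gz", voxel_size=vs,
                 description="chi ppm")
    with open(out / "structures.tsv", "w") as fh:
        fh.write("label\tname\tchi_ppm\n")
        for lab, (name, v) in sorted(ph.structure_table.items()):
            fh.write(f"{lab}\t{name}\t{v}\n")

    record = {
        "config": cfg,
        "seed": seed,
        "input_hashes": {"chi_truth": _hash_array(ph.chi),
                         "phase": _hash_array(series.phase)},
        "pipeline": provenance,
        "gtv_metrics_ppm": em,
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(record, fh, indent=2, default=str)
    return record
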
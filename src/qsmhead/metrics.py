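"""Error metrics between estimated and ground-truth volumes.

RMSE and MAE over a mask, plus a per-anatomical-structure report with
NRMSE.  The NRMSE normalizer is the RMS of the truth over the structure
by default (switchable to its range); structures whose truth is
identically zero report NaN rather than dividing by zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["error_metrics", "per_structure_report", "DEFAULT_STRUCTURES"]

#: Deep-gray / tissue structures conventionally reported for brain QSM.
DEFAULT_STRUCTURES = [
    "caudate", "globus_pallidus", "putamen", "red_nucleus",
    "dentate_nucleus", "SN_STN", "thalamus", "WM", "GM", "CSF",
    "blood", "fat", "muscle",
]


def error_metrics(est: np.ndarray, truth: np.ndarray,
                  mask: np.ndarray) -> dict[str, float]:
    """RMSE and MAE of est - truth over the mask."""
    est = np.asarray(est, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if est.shape != truth.shape:
        raise ValueError(f"shape mismatch: {est.shape} vs {truth.shape}")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    d = est[mask] - truth[mask]
    return {"RMSE": float(np.sqrt((d**2).mean())), "MAE": float(np.abs(d).mean())}


def per_structure_report(est: np.ndarray, truth: np.ndarray, labels: np.ndarray,
                         structures: list[str],
                         name_to_id: dict[str, int] | None = None,
                         normalizer: str = "rms") -> pd.DataFrame:
    """Per-structure RMSE / MAE / NRMSE table, in the requested order.

    ``name_to_id`` maps structure names to label IDs (defaults to the
    structure's position in ``structures`` + 1).  Missing structures get a
    row with NaN metrics and ``present=False`` rather than failing.
    """
    if normalizer not in ("rms", "range"):
        raise ValueError("normalizer must be 'rms' or 'range'")
    labels = np.asarray(labels)
    if name_to_id is None:
        name_to_id = {n: i + 1 for i, n in enumerate(structures)}
    rows = []
    for name in structures:
        sid = name_to_id.get(name)
        m = labels == sid if sid is not None else np.zeros(labels.shape, bool)
        if not m.any():
            rows.append({"structure": name, "present": False,
                         "RMSE": np.nan, "MAE": np.nan, "NRMSE": np.nan})
            continue
        em = error_metrics(est, truth, m)
        t = np.asarray(truth, dtype=float)[m]
        if normalizer == "rms":
            norm = float(np.sqrt((t**2).mean()))
        else:
            norm = float(np.ptp(t))
        nrmse = em["RMSE"] / norm if norm > 0 else np.nan
        rows.append({"structure": name, "present": True,
                     "RMSE": em["RMSE"], "MAE": em["MAE"], "NRMSE": nrmse})
    return pd.DataFrame(rows)


def plot_nrmse_radar(report: pd.DataFrame, ax=None):
    """Radar plot of per-structure NRMSE (matplotlib, optional)."""
    import matplotlib.pyplot as plt

    rep = report[report["present"] & np.isfinite(report["NRMSE"])]
    n = len(rep)
    if n == 0:
        raise ValueError("no finite NRMSE values to plot")
    angles = np.linspace(0, 2 * np.pi, n, endpoint=False)
    values = rep["NRMSE"].to_numpy()
    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    ax.plot(np.r_[angles, angles[:1]], np.r_[values, values[:1]])
    ax.fill(np.r_[angles, angles[:1]], np.r_[values, values[:1]], alpha=0.25)
    ax.set_xticks(angles)
    ax.set_xticklabels(rep["structure"])
    return ax
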
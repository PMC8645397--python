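"""Seed-based resting-state functional connectivity.

A seed ROI's mean BOLD time series is correlated (Pearson) with every
in-mask voxel, and the correlation map is variance-stabilized by the
Fisher-Z transform Q = 0.5 * ln((1 + r) / (1 - r)), which makes the map
values approximately normal and therefore suitable for group averaging
and contrasts.  Voxels whose series have zero variance yield an undefined
correlation and are stored as NaN (missing), never as 0, so that group
means are not biased toward the null.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import DegenerateSignalError, KurticaError, ShapeMismatchError
from .preprocess import Mask3D, Volume4D

__all__ = [
    "ConnectivityMap",
    "extract_seed_timeseries",
    "correlation_map",
    "fisher_z",
    "inverse_fisher_z",
    "group_mean_connectivity",
    "save_connectivity_map",
]


@dataclass
class ConnectivityMap:
    """Voxelwise Pearson r and Fisher-Z (Q) maps for one seed.

    ``r`` and ``q`` are 3-D arrays, NaN outside the mask and at degenerate
    (zero-variance) voxels; ``n_degenerate`` counts the latter and
    ``n_saturated`` the voxels with |r| = 1 (infinite Q).
    """

    r: np.ndarray
    q: np.ndarray
    seed: Mask3D
    mask: Mask3D
    n_degenerate: int = 0
    n_saturated: int = 0


def extract_seed_timeseries(v: Volume4D, roi: Mask3D) -> np.ndarray:
    """Unweighted mean of the in-ROI voxel series at each time point."""
    if roi.data.shape != v.spatial_shape:
        raise ShapeMismatchError(
            f"ROI shape {roi.data.shape} != volume spatial shape {v.spatial_shape}"
        )
    if roi.n_voxels == 0:
        raise KurticaError("empty seed ROI")
    return v.data[roi.data].mean(axis=0)


def correlation_map(
    v: Volume4D, seed_ts: np.ndarray, mask: Mask3D, seed_roi: Mask3D | None = None
) -> ConnectivityMap:
    """Pearson correlation of every in-mask voxel with the seed series.

    Zero-variance voxels are recorded as NaN and counted.  The returned
    map also carries the Fisher-Z transform of r.
    """
    seed_ts = np.asarray(seed_ts, dtype=np.float64).ravel()
    if mask.data.shape != v.spatial_shape:
        raise ShapeMismatchError(
            f"mask shape {mask.data.shape} != volume spatial shape {v.spatial_shape}"
        )
    if seed_ts.size != v.nt:
        raise ShapeMismatchError(
            f"seed series length {seed_ts.size} != series length {v.nt}"
        )
    sc = seed_ts - seed_ts.mean()
    seed_ss = float(sc @ sc)
    if seed_ss <= 0.0:
        raise DegenerateSignalError("constant seed time series")
    y = v.data[mask.data]  # (n_vox, nt)
    yc = y - y.mean(axis=1, keepdims=True)
    ss = np.einsum("ij,ij->i", yc, yc)
    degenerate = ss <= 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        r_vals = (yc @ sc) / np.sqrt(ss * seed_ss)
    r_vals = np.clip(r_vals, -1.0, 1.0)
    r_vals[degenerate] = np.nan
    r = np.full(v.spatial_shape, np.nan)
    r[mask.data] = r_vals
    q = fisher_z(r)
    n_sat = int(np.sum(np.abs(r_vals[~degenerate]) == 1.0))
    if seed_roi is None:
        seed_roi = Mask3D(data=np.zeros(v.spatial_shape, dtype=bool), affine=mask.affine)
    return ConnectivityMap(
        r=r,
        q=q,
        seed=seed_roi,
        mask=mask,
        n_degenerate=int(degenerate.sum()),
        n_saturated=n_sat,
    )


def fisher_z(r_map: np.ndarray) -> np.ndarray:
    """Fisher-Z: Q = 0.5 * ln((1 + r) / (1 - r)), elementwise (natural log).

    |r| = 1 maps to signed infinity; |r| > 1 raises.  NaNs propagate.
    """
    r_map = np.asarray(r_map, dtype=np.float64)
    finite = r_map[np.isfinite(r_map)]
    if np.any(np.abs(finite) > 1.0):
        raise KurticaError("correlation values must satisfy |r| <= 1")
    with np.errstate(divide="ignore"):
        return np.arctanh(r_map)


def inverse_fisher_z(q_map: np.ndarray) -> np.ndarray:
    """Inverse transform: r = tanh(Q)."""
    return np.tanh(np.asarray(q_map, dtype=np.float64))


def group_mean_connectivity(
    maps: Sequence[ConnectivityMap], group_labels: Sequence
) -> tuple[dict, np.ndarray]:
    """Per-group voxelwise mean Q maps and the A-minus-B difference map.

    Means are taken over non-missing (non-NaN) values.  Exactly two groups
    are required for the difference map; group order follows first
    appearance in ``group_labels``.
    """
    if len(maps) != len(group_labels):
        raise KurticaError("one group label per map is required")
    if len(maps) == 0:
        raise KurticaError("need at least one map")
    ref_mask = maps[0].mask.data
    for m in maps:
        if m.mask.data.shape != ref_mask.shape or not np.array_equal(m.mask.data, ref_mask):
            raise ShapeMismatchError("all maps must share a common analysis mask")
    groups: list = []
    for g in group_labels:
        if g not in groups:
            groups.append(g)
    means: dict = {}
    for g in groups:
        stack = np.stack([m.q for m, lbl in zip(maps, group_labels) if lbl == g])
        with np.errstate(invalid="ignore"):
            means[g] = np.nanmean(stack, axis=0)
    if len(groups) != 2:
        raise KurticaError(f"difference map requires exactly 2 groups, got {len(groups)}")
    diff = means[groups[0]] - means[groups[1]]
    return means, diff


def save_connectivity_map(cmap: ConnectivityMap, out_dir: str | Path) -> None:
    """Write r and Q as NIfTI plus a JSON sidecar with degeneracy counts."""
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = cmap.mask.affine
    nib.save(nib.Nifti1Image(cmap.r, affine), str(out_dir / "r_map.nii"))
    nib.save(nib.Nifti1Image(cmap.q, affine), str(out_dir / "q_map.nii"))
    sidecar = {
        "seed_n_voxels": int(cmap.seed.n_voxels),
        "mask_n_voxels": int(cmap.mask.n_voxels),
        "n_degenerate": cmap.n_degenerate,
        "n_saturated": cmap.n_saturated,
    }
    (out_dir / "connectivity.json").write_text(json.dumps(sidecar, indent=1))
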
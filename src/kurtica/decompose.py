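"""Spatial ICA of a preprocessed 4D series.

In the spatial-ICA convention for fMRI the voxel patterns are the
independent sources and the time courses are the mixing columns: the
masked data matrix ``M`` (time x voxels) is reduced by PCA to ``n_comp``
dimensions and kurtosis-contrast FastICA is run with time points as
channels and voxels as samples.  Each resulting component is a z-scored
spatial map paired with a time course.

Component sign is fixed so every map has non-negative skewness (making
one-sided thresholding meaningful) and components are ordered by
descending absolute map kurtosis, a sparsity proxy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import optimize, stats

from .errors import KurticaError, ShapeMismatchError
from .ica import SignalMatrix, fastica_fit, reconstruct_sources
from .preprocess import Mask3D, Volume4D

__all__ = [
    "ComponentSet",
    "to_matrix",
    "from_matrix",
    "pca_reduce",
    "spatial_ica",
    "threshold_map",
    "match_components",
    "save_component_set",
]


@dataclass
class ComponentSet:
    """Spatial ICA result: z-scored maps plus paired time courses."""

    maps: np.ndarray  # (n_comp, n_voxels_in_mask)
    time_courses: np.ndarray  # (nt, n_comp)
    mask: Mask3D
    explained_variance: np.ndarray
    order: np.ndarray
    kurtoses: np.ndarray
    converged: np.ndarray
    seed: int

    @property
    def n_comp(self) -> int:
        return self.maps.shape[0]

    def map_volume(self, comp: int) -> np.ndarray:
        """The component map as a 3-D array (zeros outside the mask)."""
        out = np.zeros(self.mask.data.shape, dtype=np.float64)
        _set_masked(out, self.mask, self.maps[comp])
        return out


def _mask_indices(mask: Mask3D) -> np.ndarray:
    """Flat indices of in-mask voxels in x-fastest (Fortran) raster order."""
    return np.flatnonzero(mask.data.ravel(order="F"))


def _set_masked(vol3d: np.ndarray, mask: Mask3D, values: np.ndarray) -> None:
    flat = vol3d.ravel(order="F")
    flat[_mask_indices(mask)] = values
    vol3d[...] = flat.reshape(vol3d.shape, order="F")


def to_matrix(v: Volume4D, mask: Mask3D) -> tuple[np.ndarray, np.ndarray]:
    """Flatten the masked series to (nt x n_voxels) plus its voxel index map.

    Column ``j`` holds the time series of the ``j``-th in-mask voxel in
    x-fastest raster order; the returned index array inverts the
    flattening (``volume.ravel(order='F')[index_map] = matrix[t]``).
    """
    if mask.data.shape != v.spatial_shape:
        raise ShapeMismatchError(
            f"mask shape {mask.data.shape} != volume spatial shape {v.spatial_shape}"
        )
    idx = _mask_indices(mask)
    if idx.size == 0:
        raise KurticaError("empty mask")
    nx, ny, nz, nt = v.data.shape
    flat = v.data.reshape(nx * ny * nz, nt, order="F")
    return flat[idx].T.copy(), idx


def from_matrix(
    m: np.ndarray, index_map: np.ndarray, spatial_shape: tuple[int, int, int]
) -> np.ndarray:
    """Inverse of :func:`to_matrix`: rebuild a 4-D array (zeros off-mask)."""
    nt = m.shape[0]
    out = np.zeros((int(np.prod(spatial_shape)), nt), dtype=np.float64)
    out[index_map] = m.T
    return out.reshape(*spatial_shape, nt, order="F")


def pca_reduce(
    m: np.ndarray, n_comp: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Project the row-centered matrix onto its top principal components.

    Returns ``(reduced, explained_variance, basis)`` where ``reduced`` is
    the ``n_comp x n_samples`` projection ``basis.T @ (m - row_means)``,
    ``explained_variance`` the descending per-component variances, and
    ``basis`` the (n_rows x n_comp) orthonormal back-projection mapping
    ``reduced`` to the rank-``n_comp`` approximation of the centered data.
    """
    m = np.asarray(m, dtype=np.float64)
    if n_comp > min(m.shape):
        raise KurticaError(
            f"n_comp={n_comp} exceeds min(shape)={min(m.shape)}"
        )
    centered = m - m.mean(axis=1, keepdims=True)
    U, s, Vt = np.linalg.svd(centered, full_matrices=False)
    basis = U[:, :n_comp]
    reduced = (s[:n_comp, None]) * Vt[:n_comp]
    explained = s[:n_comp] ** 2 / m.shape[1]
    return reduced, explained, basis


def spatial_ica(
    v: Volume4D,
    mask: Mask3D,
    n_comp: int,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> ComponentSet:
    """PCA-reduce the masked series and unmix voxel patterns with FastICA."""
    m, idx = to_matrix(v, mask)
    reduced, explained, basis = pca_reduce(m, n_comp)
    if n_comp == 1:
        # a single retained dimension is determined up to sign; no rotation
        # is left for ICA to find
        scale = reduced.std(axis=1, keepdims=True)
        maps = reduced / scale
        courses = basis * scale[0, 0]
        conv = np.ones(1, dtype=bool)
    else:
        sig = SignalMatrix(reduced)
        model = fastica_fit(sig, n_comp, tol=tol, max_iter=max_iter, seed=seed)
        maps = reconstruct_sources(model, sig).data  # (n_comp, n_vox), ~unit var
        courses = basis @ model.mixing_estimate  # (nt, n_comp)
        conv = model.converged
    # z-score across in-mask voxels
    maps = (maps - maps.mean(axis=1, keepdims=True)) / maps.std(axis=1, keepdims=True)
    # sign convention: non-negative map skewness
    skew = stats.skew(maps, axis=1)
    flip = np.where(skew < 0, -1.0, 1.0)
    maps = maps * flip[:, None]
    courses = courses * flip[None, :]
    kurt = np.array([stats.kurtosis(row, fisher=True) for row in maps])
    order = np.argsort(-np.abs(kurt), kind="stable")
    return ComponentSet(
        maps=maps[order],
        time_courses=courses[:, order],
        mask=mask,
        explained_variance=explained,
        order=order,
        kurtoses=kurt[order],
        converged=conv[order],
        seed=seed,
    )


def threshold_map(c: ComponentSet, comp: int, z_thresh: float = 2.0) -> Mask3D:
    """Binary activation mask: in-mask voxels whose map value exceeds ``z_thresh``."""
    if not 0 <= comp < c.n_comp:
        raise KurticaError(f"component index {comp} out of range [0, {c.n_comp})")
    vol = np.zeros(c.mask.data.shape, dtype=bool)
    flat = vol.ravel(order="F")
    idx = _mask_indices(c.mask)
    flat[idx] = c.maps[comp] > z_thresh
    return Mask3D(data=flat.reshape(vol.shape, order="F"), affine=c.mask.affine)


def match_components(
    est: ComponentSet | np.ndarray, truth_maps: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Resolve permutation/sign ambiguity against ground-truth maps.

    Returns ``(assignment, abs_corr)``: ``assignment[i]`` is the truth row
    matched to estimated component ``i`` by the globally optimal one-to-one
    assignment maximizing total absolute spatial correlation, and
    ``abs_corr[i]`` the corresponding ``|r|``.
    """
    est_maps = est.maps if isinstance(est, ComponentSet) else np.asarray(est)
    truth_maps = np.asarray(truth_maps, dtype=np.float64)
    if est_maps.shape[1] != truth_maps.shape[1]:
        raise ShapeMismatchError(
            f"voxel counts differ: {est_maps.shape[1]} vs {truth_maps.shape[1]}"
        )
    ne, ntr = est_maps.shape[0], truth_maps.shape[0]
    corr = np.empty((ne, ntr))
    for i in range(ne):
        for j in range(ntr):
            corr[i, j] = abs(np.corrcoef(est_maps[i], truth_maps[j])[0, 1])
    row, col = optimize.linear_sum_assignment(-corr)
    assignment = np.full(ne, -1, dtype=np.int64)
    abs_corr = np.zeros(ne)
    assignment[row] = col
    abs_corr[row] = corr[row, col]
    return assignment, abs_corr


def save_component_set(c: ComponentSet, out_dir: str | Path, z_thresh: float = 2.0) -> None:
    """Persist maps (4-D NIfTI), time courses (TSV) and a JSON sidecar."""
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vols = np.stack([c.map_volume(i) for i in range(c.n_comp)], axis=-1)
    nib.save(nib.Nifti1Image(vols, c.mask.affine), str(out_dir / "component_maps.nii"))
    header = "\t".join(f"comp{i}" for i in range(c.n_comp))
    np.savetxt(
        out_dir / "time_courses.tsv",
        c.time_courses,
        delimiter="\t",
        header=header,
        comments="",
        fmt="%.17g",
    )
    sidecar = {
        "n_comp": int(c.n_comp),
        "order": c.order.tolist(),
        "kurtoses": c.kurtoses.tolist(),
        "converged": c.converged.tolist(),
        "explained_variance": c.explained_variance.tolist(),
        "seed": int(c.seed),
        "z_thresh": z_thresh,
    }
    (out_dir / "components.json").write_text(json.dumps(sidecar, indent=1))
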
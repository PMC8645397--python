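"""Resting-state fMRI preprocessing chain.

The stages mirror the standard resting-state BOLD pipeline: drop the first
volumes acquired before signal equilibrium, correct for within-TR slice
acquisition timing, remove per-voxel linear scanner drift, band-pass to the
low-frequency band of spontaneous neural activity (0.01-0.08 Hz by
default), regress out nuisance signals such as the six rigid-body motion
parameters, and spatially smooth with a Gaussian kernel (9 mm FWHM by
default).  Head-motion estimation and spatial normalization are
registration problems outside this package's scope: inputs are assumed
aligned, and motion parameters enter as a :class:`NuisanceTable`.

All temporal stages operate only inside the analysis mask (smoothing is
whole-volume by design), and every stage restores per-voxel means so that
the preprocessed series stays on its physiologic baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import ndimage, signal

from .errors import KurticaError, ShapeMismatchError

__all__ = [
    "Volume4D",
    "Mask3D",
    "NuisanceTable",
    "PreprocessConfig",
    "trim_initial_volumes",
    "slice_timing_correct",
    "detrend_linear",
    "bandpass_filter",
    "regress_nuisance",
    "smooth_gaussian",
    "run_preprocessing",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class Volume4D:
    """A BOLD series: voxel grid over time with geometry metadata."""

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    tr_seconds: float
    affine: np.ndarray
    slice_axis: int = 2

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise KurticaError(f"Volume4D data must be 4-D, got ndim={self.data.ndim}")
        if any(d < 1 for d in self.data.shape):
            raise KurticaError(f"all dimensions must be >= 1, got shape {self.data.shape}")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise KurticaError(f"voxel sizes must be > 0, got {self.voxel_size_mm}")
        if self.tr_seconds <= 0:
            raise KurticaError(f"TR must be > 0, got {self.tr_seconds}")
        if not np.all(np.isfinite(self.data)):
            raise KurticaError("Volume4D contains non-finite data")
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4):
            raise KurticaError(f"affine must be 4x4, got {self.affine.shape}")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def nt(self) -> int:
        return self.data.shape[3]


@dataclass
class Mask3D:
    """Boolean analysis / ROI mask on the same grid as a Volume4D."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise KurticaError(f"Mask3D data must be 3-D, got ndim={self.data.ndim}")
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass
class NuisanceTable:
    """Named nuisance regressors, one row per (trimmed) time point."""

    columns: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.columns, pd.DataFrame):
            self.columns = pd.DataFrame(self.columns)
        if not np.all(np.isfinite(self.columns.to_numpy())):
            raise KurticaError("nuisance table contains non-finite values")

    @property
    def nt(self) -> int:
        return len(self.columns)

    def to_tsv(self, path) -> None:
        self.columns.to_csv(path, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def from_tsv(cls, path) -> "NuisanceTable":
        return cls(pd.read_csv(path, sep="\t", float_precision="round_trip"))


def _check_mask(v: Volume4D, mask: Mask3D) -> None:
    if mask.data.shape != v.spatial_shape:
        raise ShapeMismatchError(
            f"mask shape {mask.data.shape} does not match volume spatial shape "
            f"{v.spatial_shape}"
        )


def trim_initial_volumes(v: Volume4D, n_drop: int = 10) -> Volume4D:
    """Drop the first ``n_drop`` volumes (pre-equilibrium signal)."""
    if n_drop < 0:
        raise KurticaError(f"n_drop must be >= 0, got {n_drop}")
    if v.nt <= n_drop:
        raise KurticaError(
            f"cannot drop {n_drop} volumes from a series of length {v.nt}"
        )
    return replace(v, data=v.data[..., n_drop:].copy())


def slice_timing_correct(
    v: Volume4D,
    n_slices: int | None = None,
    ref_slice: int | None = None,
) -> Volume4D:
    """Temporally align all slices to the reference slice's acquisition time.

    Assumes sequential ascending acquisition with uniform within-TR slice
    spacing: slice ``i`` (0-based) is acquired ``i * TR / n_slices`` after
    the volume onset.  Each voxel series is linearly interpolated to the
    reference slice's sample times; the first/last samples are extrapolated
    by edge-hold.  Default reference is the middle slice.
    """
    nz = v.data.shape[v.slice_axis]
    if n_slices is None:
        n_slices = nz
    if n_slices != nz:
        raise KurticaError(
            f"n_slices={n_slices} does not match volume slice count {nz} "
            f"along axis {v.slice_axis}"
        )
    if ref_slice is None:
        ref_slice = n_slices // 2
    if not 0 <= ref_slice < n_slices:
        raise KurticaError(f"ref_slice={ref_slice} outside [0, {n_slices})")
    nt = v.nt
    out = np.empty_like(v.data)
    t_index = np.arange(nt, dtype=np.float64)
    for i in range(n_slices):
        sl = [slice(None)] * 4
        sl[v.slice_axis] = i
        series = v.data[tuple(sl)]  # (..., nt)
        # acquisition offset of this slice vs the reference, in TR units
        shift = (ref_slice - i) / n_slices
        pos = np.clip(t_index + shift, 0.0, nt - 1.0)
        lo = np.floor(pos).astype(np.int64)
        hi = np.minimum(lo + 1, nt - 1)
        w = pos - lo
        out[tuple(sl)] = series[..., lo] * (1.0 - w) + series[..., hi] * w
    return replace(v, data=out)


def detrend_linear(v: Volume4D, mask: Mask3D) -> Volume4D:
    """Remove the OLS linear trend per in-mask voxel, preserving the mean."""
    _check_mask(v, mask)
    if v.nt < 3:
        raise KurticaError(f"detrend requires at least 3 time points, got {v.nt}")
    out = v.data.copy()
    y = out[mask.data]  # (n_vox, nt)
    t = np.arange(v.nt, dtype=np.float64)
    tc = t - t.mean()
    slope = (y @ tc) / (tc @ tc)
    out[mask.data] = y - slope[:, None] * tc[None, :]
    return replace(v, data=out)


def bandpass_filter(
    v: Volume4D,
    mask: Mask3D,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
    order: int = 5,
) -> Volume4D:
    """Zero-phase Butterworth band-pass per in-mask voxel.

    Means are removed before filtering and restored afterward, so constant
    series pass unchanged.  Forward-backward application (``filtfilt``)
    avoids phase shifts that would corrupt downstream correlations.
    """
    _check_mask(v, mask)
    nyquist = 1.0 / (2.0 * v.tr_seconds)
    if not 0.0 < low_hz < high_hz < nyquist:
        raise KurticaError(
            f"band ({low_hz}, {high_hz}) Hz must satisfy 0 < low < high < "
            f"Nyquist = {nyquist} Hz for TR = {v.tr_seconds} s"
        )
    sos = signal.butter(
        order, [low_hz, high_hz], btype="bandpass", fs=1.0 / v.tr_seconds, output="sos"
    )
    out = v.data.copy()
    y = out[mask.data]
    means = y.mean(axis=1, keepdims=True)
    padlen = min(v.nt - 1, 3 * (2 * sos.shape[0] + 1))
    filtered = signal.sosfiltfilt(sos, y - means, axis=1, padlen=padlen)
    out[mask.data] = filtered + means
    return replace(v, data=out)


def regress_nuisance(v: Volume4D, mask: Mask3D, nuis: NuisanceTable) -> Volume4D:
    """OLS-residualize each in-mask voxel on [intercept | nuisance columns].

    The voxel mean is restored after residualization.  A rank-deficient
    design raises with the names of the collinear columns.
    """
    _check_mask(v, mask)
    if nuis.nt != v.nt:
        raise ShapeMismatchError(
            f"nuisance table has {nuis.nt} rows but series length is {v.nt}"
        )
    X = np.column_stack([np.ones(v.nt), nuis.columns.to_numpy(dtype=np.float64)])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns via pivoted QR on the standardized design
        _, _, piv = sla.qr(X, mode="economic", pivoting=True)
        bad = sorted(piv[rank:])
        names = ["intercept"] + list(nuis.columns.columns)
        raise KurticaError(
            "rank-deficient nuisance design; collinear columns: "
            + ", ".join(names[i] for i in bad)
        )
    out = v.data.copy()
    y = out[mask.data]  # (n_vox, nt)
    beta, *_ = np.linalg.lstsq(X, y.T, rcond=None)
    resid = y - (X @ beta).T
    out[mask.data] = resid + y.mean(axis=1, keepdims=True)
    return replace(v, data=out)


def smooth_gaussian(
    v: Volume4D, fwhm_mm: tuple[float, float, float] = (9.0, 9.0, 9.0)
) -> Volume4D:
    """Separable Gaussian smoothing of each volume.

    Kernel width per axis is ``sigma_voxels = FWHM_mm * FWHM_TO_SIGMA /
    voxel_size_mm``; reflecting boundary, kernel truncated at 4 sigma.
    Whole-volume (not mask-restricted) by design.
    """
    if any(f < 0 for f in fwhm_mm):
        raise KurticaError(f"FWHM components must be >= 0, got {fwhm_mm}")
    sigma_vox = [
        f * FWHM_TO_SIGMA / vs for f, vs in zip(fwhm_mm, v.voxel_size_mm)
    ]
    if all(s == 0.0 for s in sigma_vox):
        return replace(v, data=v.data.copy())
    out = np.empty_like(v.data)
    for t in range(v.nt):
        out[..., t] = ndimage.gaussian_filter(
            v.data[..., t], sigma=sigma_vox, mode="reflect", truncate=4.0
        )
    return replace(v, data=out)


@dataclass
class PreprocessConfig:
    """Which stages run, and with what parameters.

    Defaults follow the standard chain: drop 10 volumes, slice-timing to
    the middle slice, linear detrend, 0.01-0.08 Hz band-pass, nuisance
    regression (when a table is supplied), 9 mm FWHM smoothing.
    """

    trim: bool = True
    n_drop: int = 10
    slice_timing: bool = True
    ref_slice: int | None = None
    detrend: bool = True
    bandpass: bool = True
    low_hz: float = 0.01
    high_hz: float = 0.08
    nuisance: bool = True
    smooth: bool = True
    fwhm_mm: tuple[float, float, float] = (9.0, 9.0, 9.0)

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["fwhm_mm"] = list(self.fwhm_mm)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessConfig":
        kwargs = dict(d)
        if "fwhm_mm" in kwargs:
            kwargs["fwhm_mm"] = tuple(kwargs["fwhm_mm"])
        return cls(**kwargs)


def run_preprocessing(
    v: Volume4D,
    mask: Mask3D,
    nuis: NuisanceTable | None = None,
    config: PreprocessConfig | None = None,
) -> tuple[Volume4D, list[str]]:
    """Run the enabled stages in pipeline order; return (volume, provenance log).

    Order: trim -> slice timing -> detrend -> band-pass -> nuisance
    regression -> smoothing.  The provenance log records each executed
    stage with its parameters.
    """
    if config is None:
        config = PreprocessConfig()
    log: list[str] = []
    out = v
    if config.trim:
        out = trim_initial_volumes(out, config.n_drop)
        log.append(f"trim_initial_volumes n_drop={config.n_drop}")
        # regressors recorded for the full acquisition follow the trim
        if nuis is not None and nuis.nt == v.nt:
            nuis = NuisanceTable(nuis.columns.iloc[config.n_drop :].reset_index(drop=True))
    if config.slice_timing:
        nz = out.data.shape[out.slice_axis]
        ref = config.ref_slice if config.ref_slice is not None else nz // 2
        out = slice_timing_correct(out, n_slices=nz, ref_slice=ref)
        log.append(f"slice_timing_correct n_slices={nz} ref_slice={ref}")
    if config.detrend:
        out = detrend_linear(out, mask)
        log.append("detrend_linear")
    if config.bandpass:
        out = bandpass_filter(out, mask, config.low_hz, config.high_hz)
        log.append(f"bandpass_filter low_hz={config.low_hz} high_hz={config.high_hz}")
    if config.nuisance:
        if nuis is None:
            raise KurticaError("nuisance stage enabled but no NuisanceTable supplied")
        out = regress_nuisance(out, mask, nuis)
        log.append(f"regress_nuisance k={nuis.columns.shape[1]}")
    if config.smooth:
        out = smooth_gaussian(out, config.fwhm_mm)
        log.append(f"smooth_gaussian fwhm_mm={tuple(config.fwhm_mm)}")
    return out, log
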
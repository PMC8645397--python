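"""Synthetic ground-truth data: toy source mixtures and 4D fMRI phantoms.

The toy generator produces independent non-Gaussian sources (uniform,
square, sawtooth, sinusoid, at most one Gaussian) mixed by a known matrix
— the canonical blind-source-separation test bed.

The fMRI phantom emulates a resting-state acquisition at desk scale: a
24 x 24 x 8 voxel grid (3 mm isotropic) over 120 volumes at TR = 2 s,
with spatially compact Gaussian activation sources whose time courses are
band-limited to 0.01-0.08 Hz, a linear scanner drift, additive Gaussian
noise, and six smooth pseudo-motion nuisance regressors.  SNR is defined
as source amplitude over noise standard deviation at the source peak.
Every generator is a pure function of its spec and seed.

A two-group variant couples a target region's time course to a seed
region's at correlation ``rho_control`` in controls and ``rho_control +
effect_delta`` in the observation group, emulating a between-group
functional-connectivity difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import KurticaError
from .ica import SignalMatrix
from .preprocess import Mask3D, NuisanceTable, Volume4D

__all__ = [
    "SourceSpec",
    "PhantomSpec",
    "PhantomTruth",
    "TwoGroupTruth",
    "make_toy_mixtures",
    "make_fmri_phantom",
    "make_two_group_dataset",
    "default_phantom_spec",
]

TOY_KINDS = ("uniform", "square", "sawtooth", "sinusoid", "gaussian")
COURSE_KINDS = ("block", "sinusoid", "band-limited-noise")


@dataclass
class SourceSpec:
    """One spatially compact activation source."""

    center_voxel: tuple[int, int, int]
    fwhm_mm: float = 25.0
    time_course_kind: str = "band-limited-noise"
    frequency_hz: float | None = None  # sinusoid frequency or 1/block period
    amplitude: float = 1.0


@dataclass
class PhantomSpec:
    """Full description of one synthetic fMRI acquisition."""

    shape: tuple[int, int, int] = (24, 24, 8)
    nt: int = 120
    tr_seconds: float = 2.0
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    sources: list[SourceSpec] = field(default_factory=list)
    noise_sigma: float = 0.5
    drift_slope: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        nyquist = 1.0 / (2.0 * self.tr_seconds)
        if self.noise_sigma < 0:
            raise KurticaError(f"invalid field noise_sigma: must be >= 0, got {self.noise_sigma}")
        if self.nt < 4:
            raise KurticaError(f"invalid field nt: must be >= 4, got {self.nt}")
        for i, s in enumerate(self.sources):
            if s.time_course_kind not in COURSE_KINDS:
                raise KurticaError(
                    f"invalid field time_course_kind of source {i}: {s.time_course_kind!r}"
                )
            if s.frequency_hz is not None and not 0.0 < s.frequency_hz < nyquist:
                raise KurticaError(
                    f"invalid field frequency_hz of source {i}: {s.frequency_hz} "
                    f"outside (0, {nyquist})"
                )
            if not all(0 <= c < n for c, n in zip(s.center_voxel, self.shape)):
                raise KurticaError(
                    f"invalid field center_voxel of source {i}: {s.center_voxel} "
                    f"outside grid {self.shape}"
                )
            if s.fwhm_mm <= 0:
                raise KurticaError(f"invalid field fwhm_mm of source {i}: {s.fwhm_mm}")


@dataclass
class PhantomTruth:
    """Exact ground truth emitted next to a phantom."""

    maps: list[np.ndarray]  # per-source non-negative 3-D weights, peak 1
    masks: list[Mask3D]  # weight > half-maximum
    time_courses: np.ndarray  # (nt, n_sources), unit variance
    group_label: str | None = None
    effect: dict | None = None


@dataclass
class TwoGroupTruth:
    """Shared ground truth of a two-group connectivity dataset."""

    seed_mask: Mask3D
    target_mask: Mask3D
    seed_map: np.ndarray
    target_map: np.ndarray
    rho_control: float
    rho_observation: float
    effect_delta: float


def _standardize(s: np.ndarray) -> np.ndarray:
    s = s - s.mean()
    sd = s.std()
    if sd <= 0:
        raise KurticaError("degenerate source: zero variance")
    return s / sd


def _toy_source(kind: str, n: int, rng: np.random.Generator) -> np.ndarray:
    t = np.arange(n)
    if kind == "uniform":
        return rng.uniform(-np.sqrt(3.0), np.sqrt(3.0), size=n)
    if kind == "square":
        phase = rng.uniform(0, 2 * np.pi)
        return sps.square(2 * np.pi * t / 313.0 + phase)
    if kind == "sawtooth":
        phase = rng.uniform(0, 2 * np.pi)
        return sps.sawtooth(2 * np.pi * t / 247.0 + phase)
    if kind == "sinusoid":
        phase = rng.uniform(0, 2 * np.pi)
        return np.sin(2 * np.pi * t / 199.0 + phase)
    if kind == "gaussian":
        return rng.standard_normal(n)
    raise KurticaError(f"unknown toy source kind {kind!r}; choose from {TOY_KINDS}")


def make_toy_mixtures(
    n_sources: int,
    n_samples: int,
    kinds: Sequence[str],
    mixing: np.ndarray | str = "random",
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, SignalMatrix]:
    """Independent unit-variance sources and their exact linear mixture.

    ``mixing`` may be an explicit matrix or ``"random"`` (seeded standard
    normal).  Requesting more than one Gaussian source fails: a mixture of
    Gaussians is rotationally invariant and ICA cannot identify it.
    """
    if len(kinds) != n_sources:
        raise KurticaError(f"need {n_sources} kinds, got {len(kinds)}")
    if sum(k == "gaussian" for k in kinds) > 1:
        raise KurticaError(
            "at most one Gaussian source is allowed: ICA cannot separate "
            "multiple Gaussian sources"
        )
    rng = np.random.default_rng(seed)
    sources = np.vstack(
        [_standardize(_toy_source(k, n_samples, rng)) for k in kinds]
    )
    if isinstance(mixing, str):
        if mixing != "random":
            raise KurticaError(f"mixing must be a matrix or 'random', got {mixing!r}")
        A = rng.standard_normal((n_sources, n_sources))
    else:
        A = np.asarray(mixing, dtype=np.float64)
        if A.shape != (n_sources, n_sources):
            raise KurticaError(f"mixing must be {n_sources}x{n_sources}, got {A.shape}")
    observations = SignalMatrix(A @ sources)
    return sources, A, observations


def default_phantom_spec(seed: int = 0, snr: float = 2.0) -> PhantomSpec:
    """The canonical three-source phantom: 24 x 24 x 8 x 120, TR 2 s.

    Sources: a 0.03 Hz sinusoid, a 25 s-period block, and a 0.01-0.08 Hz
    band-limited noise course, each a 25 mm-FWHM blob of amplitude 1 —
    compact clusters covering a realistic fraction (about 6% each) of the
    analysis volume.
    ``noise_sigma = 1 / snr`` realizes the requested peak SNR.
    """
    sources = [
        SourceSpec(center_voxel=(6, 6, 2), time_course_kind="sinusoid", frequency_hz=0.03),
        SourceSpec(center_voxel=(17, 7, 5), time_course_kind="block", frequency_hz=0.04),
        SourceSpec(center_voxel=(9, 17, 4), time_course_kind="band-limited-noise"),
    ]
    return PhantomSpec(sources=sources, noise_sigma=1.0 / snr, seed=seed)


def _gaussian_map(
    shape: tuple[int, int, int],
    voxel_size_mm: tuple[float, float, float],
    center: tuple[int, int, int],
    fwhm_mm: float,
) -> np.ndarray:
    sigma_mm = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    grids = np.meshgrid(
        *[np.arange(n) * v for n, v in zip(shape, voxel_size_mm)], indexing="ij"
    )
    d2 = sum(
        (g - c * v) ** 2 for g, c, v in zip(grids, center, voxel_size_mm)
    )
    return np.exp(-d2 / (2.0 * sigma_mm**2))


def _band_limited_noise(nt: int, tr: float, rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal(nt)
    sos = sps.butter(5, [0.01, 0.08], btype="bandpass", fs=1.0 / tr, output="sos")
    padlen = min(nt - 1, 3 * (2 * sos.shape[0] + 1))
    return sps.sosfiltfilt(sos, white, padlen=padlen)


def _phantom_course(
    src: SourceSpec, nt: int, tr: float, rng: np.random.Generator
) -> np.ndarray:
    t = np.arange(nt) * tr
    if src.time_course_kind == "sinusoid":
        f = src.frequency_hz if src.frequency_hz is not None else 0.03
        phase = rng.uniform(0, 2 * np.pi)
        return _standardize(np.sin(2 * np.pi * f * t + phase))
    if src.time_course_kind == "block":
        f = src.frequency_hz if src.frequency_hz is not None else 0.04
        phase = rng.uniform(0, 2 * np.pi)
        return _standardize(sps.square(2 * np.pi * f * t + phase))
    if src.time_course_kind == "band-limited-noise":
        return _standardize(_band_limited_noise(nt, tr, rng))
    raise KurticaError(f"unknown time_course_kind {src.time_course_kind!r}")


def _pseudo_motion(nt: int, rng: np.random.Generator) -> NuisanceTable:
    """Six smooth random-walk columns standing in for rigid-body motion traces."""
    names = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
    cols = {}
    for name in names:
        walk = np.cumsum(rng.standard_normal(nt)) * 0.05
        kernel = np.exp(-0.5 * (np.arange(-8, 9) / 3.0) ** 2)
        kernel /= kernel.sum()
        smooth = np.convolve(np.pad(walk, 8, mode="edge"), kernel, mode="valid")
        cols[name] = smooth
    return NuisanceTable(pd.DataFrame(cols))


def _render_phantom(
    spec: PhantomSpec, courses: np.ndarray, rng: np.random.Generator
) -> tuple[Volume4D, PhantomTruth, NuisanceTable]:
    """Assemble maps x courses + drift + noise into a Volume4D."""
    maps, masks = [], []
    affine = np.diag([*spec.voxel_size_mm, 1.0])
    data = np.zeros((*spec.shape, spec.nt))
    for k, src in enumerate(spec.sources):
        w = _gaussian_map(spec.shape, spec.voxel_size_mm, src.center_voxel, src.fwhm_mm)
        maps.append(w)
        masks.append(Mask3D(data=w > 0.5 * w.max(), affine=affine))
        data += src.amplitude * w[..., None] * courses[:, k]
    t_index = np.arange(spec.nt, dtype=np.float64)
    data += spec.drift_slope * t_index
    if spec.noise_sigma > 0:
        data += rng.normal(0.0, spec.noise_sigma, size=data.shape)
    vol = Volume4D(
        data=data,
        voxel_size_mm=spec.voxel_size_mm,
        tr_seconds=spec.tr_seconds,
        affine=affine,
    )
    truth = PhantomTruth(maps=maps, masks=masks, time_courses=courses)
    nuis = _pseudo_motion(spec.nt, rng)
    return vol, truth, nuis


def make_fmri_phantom(
    spec: PhantomSpec,
) -> tuple[Volume4D, PhantomTruth, NuisanceTable]:
    """Generate one phantom acquisition with exact ground truth.

    The volume is the sum over sources of (Gaussian spatial map) x (unit
    variance time course) scaled by amplitude, plus a linear drift of
    ``drift_slope`` per volume and white Gaussian noise of standard
    deviation ``noise_sigma``.  The emitted nuisance table holds six
    smooth pseudo-motion regressors.
    """
    spec.validate()
    if not spec.sources:
        raise KurticaError("invalid field sources: at least one source required")
    rng = np.random.default_rng(spec.seed)
    courses = np.column_stack(
        [_phantom_course(s, spec.nt, spec.tr_seconds, rng) for s in spec.sources]
    )
    return _render_phantom(spec, courses, rng)


def make_two_group_dataset(
    n_per_group: int,
    base_spec: PhantomSpec | None = None,
    effect_delta: float = 0.5,
    seed: int = 0,
    rho_control: float = 0.25,
) -> tuple[list[tuple[Volume4D, str]], TwoGroupTruth]:
    """Two subject groups differing in seed-target coupling strength.

    Sources 0 and 1 of ``base_spec`` act as seed and target regions.  The
    target time course is ``rho * seed_course + sqrt(1 - rho^2) * noise``
    with ``rho = rho_control`` for controls and ``rho_control +
    effect_delta`` for the observation group.  Per-subject randomness is
    spawned deterministically from the master seed.  Returns subjects as
    ``(volume, label)`` pairs with labels "observation" and "control".
    """
    if n_per_group < 1:
        raise KurticaError(f"n_per_group must be >= 1, got {n_per_group}")
    rho_obs = rho_control + effect_delta
    if not -1.0 < rho_obs < 1.0 or not -1.0 < rho_control < 1.0:
        raise KurticaError(
            f"coupling out of range: rho_control={rho_control}, "
            f"rho_observation={rho_obs} must lie in (-1, 1)"
        )
    if base_spec is None:
        base_spec = PhantomSpec(
            sources=[
                SourceSpec(center_voxel=(6, 6, 2), time_course_kind="band-limited-noise"),
                SourceSpec(center_voxel=(17, 17, 5), time_course_kind="band-limited-noise"),
            ],
            seed=seed,
        )
    if len(base_spec.sources) < 2:
        raise KurticaError("base_spec needs at least 2 sources (seed and target)")
    base_spec.validate()
    children = np.random.SeedSequence(seed).spawn(2 * n_per_group)
    subjects: list[tuple[Volume4D, str]] = []
    truth_ref: TwoGroupTruth | None = None
    for i, child in enumerate(children):
        label = "observation" if i < n_per_group else "control"
        rho = rho_obs if label == "observation" else rho_control
        rng = np.random.default_rng(child)
        seed_course = _phantom_course(
            base_spec.sources[0], base_spec.nt, base_spec.tr_seconds, rng
        )
        indep = _phantom_course(
            base_spec.sources[1], base_spec.nt, base_spec.tr_seconds, rng
        )
        target_course = _standardize(
            rho * seed_course + np.sqrt(1.0 - rho**2) * indep
        )
        extra = [
            _phantom_course(s, base_spec.nt, base_spec.tr_seconds, rng)
            for s in base_spec.sources[2:]
        ]
        courses = np.column_stack([seed_course, target_course, *extra])
        vol, truth, _ = _render_phantom(base_spec, courses, rng)
        subjects.append((vol, label))
        if truth_ref is None:
            truth_ref = TwoGroupTruth(
                seed_mask=truth.masks[0],
                target_mask=truth.masks[1],
                seed_map=truth.maps[0],
                target_map=truth.maps[1],
                rho_control=rho_control,
                rho_observation=rho_obs,
                effect_delta=effect_delta,
            )
    assert truth_ref is not None
    return subjects, truth_ref
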
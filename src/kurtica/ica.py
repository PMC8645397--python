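"""Kurtosis-contrast FastICA for blind source separation.

Implements the linear instantaneous mixing model ``K = X S``: ``K`` is an
``n_channels x n_samples`` matrix of observed signals, ``X`` the unknown
mixing matrix and ``S`` the mutually independent, non-Gaussian sources.
Separation proceeds in two stages:

1. *Whitening* — remove channel means and linearly decorrelate so the data
   have identity sample covariance (eigendecomposition of the covariance,
   components kept in descending-eigenvalue order).
2. *Fixed-point iteration* — extract one unmixing vector ``a`` at a time by
   iterating the kurtosis fixed-point update ``a+ = E{z (a'z)^3} - 3a`` on
   whitened data ``z``, Gram-Schmidt-deflating against previously accepted
   vectors and renormalizing.  Excess kurtosis ``E{s_hat^4} - 3`` is the
   non-Gaussianity contrast; it vanishes for Gaussians and is scale
   invariant, so extrema of ``|kurt(a'z)|`` on the unit sphere identify
   source directions.

A stochastic-gradient alternative (``fastica_fit_gradient``) performing
plain gradient ascent on ``|kurtosis|`` is provided for comparison; the
fixed-point variant is the default entry point.

Expectations ``E{.}`` are always sample means over columns.  All random
initialization is driven by a mandatory integer seed, making every fit
bit-reproducible.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DegenerateSignalError, InsufficientRankError, KurticaError, ShapeMismatchError

__all__ = [
    "SignalMatrix",
    "WhiteningResult",
    "UnmixingModel",
    "SourceEstimate",
    "center_and_whiten",
    "sample_kurtosis",
    "fastica_fit",
    "fastica_fit_gradient",
    "reconstruct_sources",
    "estimate_mixing",
    "read_signal_tsv",
    "write_signal_tsv",
    "save_model_json",
    "load_model_json",
]

#: eigenvalues below RANK_RTOL * largest are treated as rank deficiency
RANK_RTOL = 1e-10


@dataclass
class SignalMatrix:
    """Observed multichannel signals, one channel per row."""

    data: np.ndarray
    channel_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise KurticaError(f"signal matrix must be 2-D, got ndim={self.data.ndim}")
        n_channels, n_samples = self.data.shape
        if n_channels < 2:
            raise KurticaError(f"need at least 2 channels, got {n_channels}")
        if n_samples <= n_channels:
            raise KurticaError(
                f"need more samples than channels, got {n_samples} samples "
                f"for {n_channels} channels"
            )
        if not np.all(np.isfinite(self.data)):
            raise KurticaError("signal matrix contains non-finite entries")
        if self.channel_labels is not None and len(self.channel_labels) != n_channels:
            raise KurticaError("channel_labels length does not match channel count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class WhiteningResult:
    """Affine transform taking observed channels to unit-covariance space.

    ``whiten @ (x - mean[:, None])`` has identity sample covariance;
    ``dewhiten`` is its right inverse (``whiten @ dewhiten = I``).
    """

    mean: np.ndarray
    whiten: np.ndarray
    dewhiten: np.ndarray
    n_comp: int


@dataclass
class UnmixingModel:
    """A fitted ICA: whitening plus orthonormal unmixing rows.

    ``rows`` operate in whitened space; the composed observed-space
    unmixing is ``rows @ whitening.whiten`` and ``mixing_estimate`` is its
    pseudoinverse (the estimated mixing matrix, column per component).
    """

    whitening: WhiteningResult
    rows: np.ndarray
    mixing_estimate: np.ndarray
    kurtoses: np.ndarray
    converged: np.ndarray
    iterations: np.ndarray
    seed: int | None = None
    tol: float = 1e-6

    @property
    def n_comp(self) -> int:
        return self.rows.shape[0]


@dataclass
class SourceEstimate:
    """Recovered source signals (rows), with the model that produced them."""

    data: np.ndarray
    model: UnmixingModel = field(repr=False)


def center_and_whiten(x: SignalMatrix, n_comp: int) -> tuple[WhiteningResult, np.ndarray]:
    """Center channels and whiten via eigendecomposition of the covariance.

    Returns the whitening transform and the whitened ``n_comp x n_samples``
    matrix (zero row means, identity sample covariance).  Components are
    ordered by descending eigenvalue.  Raises
    :class:`~kurtica.errors.InsufficientRankError` when fewer than
    ``n_comp`` eigenvalues exceed ``RANK_RTOL`` times the largest.
    """
    if not 1 <= n_comp <= x.n_channels:
        raise KurticaError(
            f"n_comp={n_comp} out of range for {x.n_channels} channels"
        )
    mean = x.data.mean(axis=1)
    centered = x.data - mean[:, None]
    cov = centered @ centered.T / x.n_samples
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    achieved_rank = int(np.sum(evals > RANK_RTOL * max(evals[0], 0.0)))
    if achieved_rank < n_comp:
        raise InsufficientRankError(achieved_rank, n_comp)
    lam = evals[:n_comp]
    E = evecs[:, :n_comp]
    whiten = (E / np.sqrt(lam)).T
    dewhiten = E * np.sqrt(lam)
    z = whiten @ centered
    return WhiteningResult(mean=mean, whiten=whiten, dewhiten=dewhiten, n_comp=n_comp), z


def sample_kurtosis(s: np.ndarray) -> float:
    """Excess kurtosis ``E{s_hat^4} - 3`` of the standardized sample.

    Zero for Gaussian data, -1.2 for a uniform distribution; invariant to
    rescaling ``s -> c*s`` for any nonzero ``c``.
    """
    s = np.asarray(s, dtype=np.float64).ravel()
    if s.size < 4:
        raise KurticaError(f"need at least 4 samples for kurtosis, got {s.size}")
    if not np.all(np.isfinite(s)):
        raise KurticaError("kurtosis input contains non-finite values")
    centered = s - s.mean()
    var = np.mean(centered**2)
    if var <= 0.0:
        raise DegenerateSignalError("degenerate signal: zero variance")
    return float(np.mean(centered**4) / var**2 - 3.0)


def _random_unit_vector(rng: np.random.Generator, dim: int) -> np.ndarray:
    v = rng.uniform(-1.0, 1.0, size=dim)
    n = np.linalg.norm(v)
    while n < 1e-12:  # vanishingly unlikely; retry for safety
        v = rng.uniform(-1.0, 1.0, size=dim)
        n = np.linalg.norm(v)
    return v / n


def _deflate(v: np.ndarray, accepted: list[np.ndarray]) -> np.ndarray:
    for w in accepted:
        v = v - np.dot(v, w) * w
    return v


def _finalize_model(
    whitening: WhiteningResult,
    rows: np.ndarray,
    z: np.ndarray,
    converged: np.ndarray,
    iterations: np.ndarray,
    seed: int,
    tol: float,
) -> UnmixingModel:
    sources = rows @ z
    kurtoses = np.array([sample_kurtosis(row) for row in sources])
    unmix_observed = rows @ whitening.whiten
    mixing_estimate = np.linalg.pinv(unmix_observed)
    return UnmixingModel(
        whitening=whitening,
        rows=rows,
        mixing_estimate=mixing_estimate,
        kurtoses=kurtoses,
        converged=converged,
        iterations=iterations,
        seed=seed,
        tol=tol,
    )


def fastica_fit(
    x: SignalMatrix,
    n_comp: int,
    tol: float = 1e-6,
    max_iter: int = 200,
    seed: int = 0,
) -> UnmixingModel:
    """Fit kurtosis-contrast FastICA by deflation.

    For each component, starting from a seeded random unit vector, iterate

        a+ = E{z (a'z)^3} - 3a

    on the whitened data ``z``, Gram-Schmidt-deflate ``a+`` against
    previously accepted rows, renormalize, and declare convergence when
    ``|<a_new, a_old>| >= 1 - tol`` (direction-invariant, so sign flips
    between iterations do not stall the test).  Components that fail to
    converge within ``max_iter`` are kept, flagged ``converged=False`` and
    reported via a warning.
    """
    whitening, z = center_and_whiten(x, n_comp)
    rng = np.random.default_rng(seed)
    accepted: list[np.ndarray] = []
    converged = np.zeros(n_comp, dtype=bool)
    iterations = np.zeros(n_comp, dtype=np.int64)
    for p in range(n_comp):
        a = _deflate(_random_unit_vector(rng, n_comp), accepted)
        a = a / np.linalg.norm(a)
        for it in range(1, max_iter + 1):
            proj = a @ z
            a_new = (z * proj**3).mean(axis=1) - 3.0 * a
            a_new = _deflate(a_new, accepted)
            nrm = np.linalg.norm(a_new)
            if nrm < 1e-12:
                # update collapsed into the span of accepted rows; restart
                a_new = _deflate(_random_unit_vector(rng, n_comp), accepted)
                nrm = np.linalg.norm(a_new)
            a_new = a_new / nrm
            iterations[p] = it
            if abs(np.dot(a_new, a)) >= 1.0 - tol:
                a = a_new
                converged[p] = True
                break
            a = a_new
        if not converged[p]:
            warnings.warn(
                f"component {p} did not converge in {max_iter} iterations",
                RuntimeWarning,
                stacklevel=2,
            )
        accepted.append(a)
    rows = np.vstack(accepted)
    return _finalize_model(whitening, rows, z, converged, iterations, seed, tol)


def fastica_fit_gradient(
    x: SignalMatrix,
    n_comp: int,
    step: float = 0.1,
    tol: float = 1e-6,
    max_iter: int = 200,
    seed: int = 0,
) -> UnmixingModel:
    """Stochastic-gradient variant of the kurtosis contrast.

    Same contract as :func:`fastica_fit`, but each iteration performs a
    gradient step on the kurtosis surface,

        a+ = a + step * sign(kurt(a'z)) * E{z (a'z)^3},

    followed by deflation and renormalization.  ``step = 0`` performs no
    optimization: the model is returned at its random initialization with
    ``converged=False`` for every component.
    """
    if step < 0:
        raise KurticaError(f"step must be >= 0, got {step}")
    whitening, z = center_and_whiten(x, n_comp)
    rng = np.random.default_rng(seed)
    accepted: list[np.ndarray] = []
    converged = np.zeros(n_comp, dtype=bool)
    iterations = np.zeros(n_comp, dtype=np.int64)
    for p in range(n_comp):
        a = _deflate(_random_unit_vector(rng, n_comp), accepted)
        a = a / np.linalg.norm(a)
        for it in range(1, max_iter + 1):
            proj = a @ z
            grad = (z * proj**3).mean(axis=1)
            kurt = np.mean(proj**4) - 3.0  # proj is unit variance in whitened space
            a_raw = a + step * np.sign(kurt) * grad
            moved = not np.array_equal(a_raw, a)
            a_new = _deflate(a_raw, accepted)
            nrm = np.linalg.norm(a_new)
            if nrm < 1e-12:
                a_new = _deflate(_random_unit_vector(rng, n_comp), accepted)
                nrm = np.linalg.norm(a_new)
            a_new = a_new / nrm
            iterations[p] = it
            # a zero-length step cannot count as convergence
            if moved and abs(np.dot(a_new, a)) >= 1.0 - tol:
                a = a_new
                converged[p] = True
                break
            a = a_new
        if not converged[p]:
            warnings.warn(
                f"component {p} did not converge in {max_iter} iterations",
                RuntimeWarning,
                stacklevel=2,
            )
        accepted.append(a)
    rows = np.vstack(accepted)
    return _finalize_model(whitening, rows, z, converged, iterations, seed, tol)


def reconstruct_sources(model: UnmixingModel, x: SignalMatrix) -> SourceEstimate:
    """Apply the fitted unmixing to observed signals: ``rows @ whiten @ (x - mean)``."""
    if x.n_channels != model.whitening.mean.shape[0]:
        raise ShapeMismatchError(
            f"model expects {model.whitening.mean.shape[0]} channels, "
            f"signal has {x.n_channels}"
        )
    centered = x.data - model.whitening.mean[:, None]
    data = model.rows @ model.whitening.whiten @ centered
    return SourceEstimate(data=data, model=model)


def estimate_mixing(model: UnmixingModel) -> np.ndarray:
    """Estimated mixing matrix: pseudoinverse of the observed-space unmixing."""
    return model.mixing_estimate.copy()


# ---------------------------------------------------------------------------
# TSV / JSON plumbing


def write_signal_tsv(x: SignalMatrix, path: str | Path) -> None:
    """One channel per row, tab-separated, 17 significant digits.

    An optional leading ``#``-prefixed line carries channel labels.
    """
    path = Path(path)
    with path.open("w") as fh:
        if x.channel_labels is not None:
            fh.write("#" + "\t".join(x.channel_labels) + "\n")
        for row in x.data:
            fh.write("\t".join(format(v, ".17g") for v in row) + "\n")


def read_signal_tsv(path: str | Path) -> SignalMatrix:
    path = Path(path)
    labels: list[str] | None = None
    rows: list[list[float]] = []
    with path.open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                labels = line[1:].split("\t")
                continue
            rows.append([float(v) for v in line.split("\t")])
    return SignalMatrix(data=np.array(rows, dtype=np.float64), channel_labels=labels)


def save_model_json(model: UnmixingModel, path: str | Path) -> None:
    payload = {
        "mean": model.whitening.mean.tolist(),
        "whiten": model.whitening.whiten.tolist(),
        "dewhiten": model.whitening.dewhiten.tolist(),
        "n_comp": model.whitening.n_comp,
        "rows": model.rows.tolist(),
        "mixing_estimate": model.mixing_estimate.tolist(),
        "kurtoses": model.kurtoses.tolist(),
        "converged": model.converged.tolist(),
        "iterations": model.iterations.tolist(),
        "seed": model.seed,
        "tol": model.tol,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model_json(path: str | Path) -> UnmixingModel:
    payload = json.loads(Path(path).read_text())
    whitening = WhiteningResult(
        mean=np.array(payload["mean"]),
        whiten=np.array(payload["whiten"]),
        dewhiten=np.array(payload["dewhiten"]),
        n_comp=int(payload["n_comp"]),
    )
    return UnmixingModel(
        whitening=whitening,
        rows=np.array(payload["rows"]),
        mixing_estimate=np.array(payload["mixing_estimate"]),
        kurtoses=np.array(payload["kurtoses"]),
        converged=np.array(payload["converged"], dtype=bool),
        iterations=np.array(payload["iterations"], dtype=np.int64),
        seed=payload["seed"],
        tol=float(payload["tol"]),
    )
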
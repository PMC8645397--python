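import numpy as np
import pytest

import kurtica as kt


@pytest.fixture(scope="session")
def two_uniform_mixture():
    """Two independent uniform sources under the fixed 2x2 mixing."""
    A = np.array([[1.0, 0.5], [0.5, 1.0]])
    sources, A, obs = kt.make_toy_mixtures(
        2, 20_000, ["uniform", "uniform"], mixing=A, seed=42
    )
    return sources, A, obs


@pytest.fixture(scope="session")
def phantom_bundle():
    """The canonical three-source phantom at SNR 2, with full-grid mask."""
    spec = kt.default_phantom_spec(seed=7, snr=2.0)
    vol, truth, nuis = kt.make_fmri_phantom(spec)
    mask = kt.Mask3D(data=np.ones(spec.shape, dtype=bool), affine=vol.affine)
    return spec, vol, truth, nuis, mask


@pytest.fixture(scope="session")
def preprocessed_phantom(phantom_bundle):
    spec, vol, truth, nuis, mask = phantom_bundle
    pre, log = kt.run_preprocessing(vol, mask, nuis)
    return pre, log


def truth_maps_flat(truth, mask):
    """Ground-truth maps flattened in the package's voxel raster order."""
    from kurtica.decompose import _mask_indices

    idx = _mask_indices(mask)
    return np.vstack([m.ravel(order="F")[idx] for m in truth.maps])


def single_voxel_volume(series, tr=2.0):
    """A 1x1x1 volume carrying one time series, with its full mask."""
    series = np.asarray(series, dtype=np.float64)
    vol = kt.Volume4D(
        data=series.reshape(1, 1, 1, -1),
        voxel_size_mm=(3.0, 3.0, 3.0),
        tr_seconds=tr,
        affine=np.eye(4),
    )
    mask = kt.Mask3D(data=np.ones((1, 1, 1), dtype=bool), affine=np.eye(4))
    return vol, mask
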
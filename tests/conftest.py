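import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def write_nifti(tmp_path):
    """Write an array to a NIfTI file with the given voxel spacing (mm)."""
    import nibabel as nib

    def _write(name, array, voxel_dims=(1.0, 1.0, 1.0)):
        affine = np.diag(list(voxel_dims) + [1.0])
        img = nib.Nifti1Image(np.asarray(array, dtype=np.float64), affine)
        path = tmp_path / name
        nib.save(img, str(path))
        return path

    return _write
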
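"""NIfTI and CSV interchange helpers.

2D grids are stored as single-slice NIfTI volumes with unit spacing;
diagrams, masks, graphs and sinograms use the CSV writers on their own
classes.
"""

from __future__ import annotations

import nibabel as nib
import numpy as np

__all__ = ["save_nifti", "load_nifti"]


def save_nifti(volume: np.ndarray, path) -> None:
    """Write a real-valued 2D (or 3D) array as a NIfTI volume."""
    arr = np.asarray(volume, dtype=np.float64)
    if np.iscomplexobj(volume):
        raise ValueError("save magnitude images, not complex arrays")
    if arr.ndim == 2:
        arr = arr[..., None]
    nib.save(nib.Nifti1Image(arr, affine=np.eye(4)), str(path))


def load_nifti(path) -> np.ndarray:
    """Read a NIfTI volume; single-slice volumes come back as 2D arrays."""
    arr = np.asarray(nib.load(str(path)).dataobj, dtype=np.float64)
    if arr.ndim == 3 and arr.shape[-1] == 1:
        arr = arr[..., 0]
    return arr
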
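"""4D BOLD volume container and NIfTI-1 I/O."""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np

__all__ = ["Volume4D", "save_volume", "load_volume", "save_int_volume"]


@dataclass
class Volume4D:
    """A voxel grid x time BOLD dataset.

    data has shape (X, Y, Z, T); tr is the repetition time in seconds.
    """

    data: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"data must be 4D, got shape {self.data.shape}")
        if self.tr <= 0:
            raise ValueError("tr must be > 0")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data must be finite")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    def timecourses(self) -> np.ndarray:
        """Flattened (n_voxels, T) view of the time courses."""
        return self.data.reshape(-1, self.n_volumes)


def save_volume(vol: Volume4D, path) -> None:
    img = nib.Nifti1Image(vol.data.astype(np.float32), affine=np.eye(4))
    img.header.set_zooms((1.0, 1.0, 1.0, vol.tr))
    img.header.set_xyzt_units(xyz="mm", t="sec")
    nib.save(img, str(path))


def load_volume(path) -> Volume4D:
    img = nib.load(str(path))
    tr = float(img.header.get_zooms()[3])
    return Volume4D(data=np.asarray(img.dataobj, dtype=float), tr=tr)


def save_int_volume(data: np.ndarray, path) -> None:
    """Write a 3D integer volume (e.g. a winner or ground-truth map)."""
    img = nib.Nifti1Image(np.asarray(data, dtype=np.int16), affine=np.eye(4))
    nib.save(img, str(path))
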
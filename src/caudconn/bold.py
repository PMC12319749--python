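"""Core in-memory containers for 4D BOLD runs and motion traces.

A :class:`BoldRun` holds a full 4D voxel grid (x, y, z, t) together with the
affine mapping voxel indices to millimetre coordinates and the repetition
time.  Task runs additionally carry a per-volume condition label series.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

MOTION_COLUMNS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]


@dataclass
class BoldRun:
    """A 4D BOLD run: ``data`` has shape (nx, ny, nz, n_volumes)."""

    data: np.ndarray
    affine: np.ndarray
    tr: float
    labels: pd.Series | None = None  # per-volume condition labels (task runs)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"BOLD data must be 4D, got shape {self.data.shape}")
        if self.tr <= 0:
            raise ValueError(f"tr must be positive, got {self.tr}")
        if self.labels is not None and len(self.labels) != self.n_volumes:
            raise ValueError(
                f"labels length {len(self.labels)} != volume count {self.n_volumes}"
            )

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def voxel_sizes(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def with_data(self, data: np.ndarray) -> "BoldRun":
        return replace(self, data=data)

    def timeseries(self, mask: np.ndarray) -> np.ndarray:
        """Extract a (n_voxels, n_volumes) array for a boolean mask or
        an (M, 3) integer voxel index array."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            return self.data[mask]
        idx = mask.reshape(-1, 3)
        return self.data[idx[:, 0], idx[:, 1], idx[:, 2]]

    def to_nifti(self) -> nib.Nifti1Image:
        img = nib.Nifti1Image(self.data.astype(np.float32), self.affine)
        img.header.set_zooms((*self.voxel_sizes, self.tr))
        return img

    def save(self, path: str | Path) -> None:
        nib.save(self.to_nifti(), str(path))
        if self.labels is not None:
            side = Path(path).with_suffix("").with_suffix("")  # strip .nii(.gz)
            pd.DataFrame(
                {"volume": np.arange(self.n_volumes), "condition": self.labels}
            ).to_csv(f"{side}_labels.tsv", sep="\t", index=False)

    @classmethod
    def load(cls, path: str | Path, tr: float | None = None) -> "BoldRun":
        img = nib.load(str(path))
        zooms = img.header.get_zooms()
        if tr is None:
            tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 2.0
        labels = None
        side = Path(path).with_suffix("").with_suffix("")
        labels_path = Path(f"{side}_labels.tsv")
        if labels_path.exists():
            labels = pd.read_csv(labels_path, sep="\t")["condition"]
        return cls(np.asarray(img.dataobj, dtype=np.float64), img.affine, tr, labels)


def save_motion(motion: pd.DataFrame, path: str | Path) -> None:
    motion[MOTION_COLUMNS].to_csv(path, sep="\t", index=False)


def load_motion(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MOTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"motion table missing columns: {missing}")
    return df[MOTION_COLUMNS]


def mask_to_indices(mask: np.ndarray) -> np.ndarray:
    """Boolean mask -> (M, 3) voxel index array in C order."""
    return np.argwhere(np.asarray(mask, dtype=bool))
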
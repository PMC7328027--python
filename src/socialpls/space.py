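"""Voxel space: grid, affine, mask, flattening contract, NIfTI I/O, peaks.

Internal voxel vectors are the in-mask voxels flattened in row-major (C)
order over the grid.  All user-facing coordinates are millimetres through
the affine (voxel index -> mm).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = ["VoxelSpace", "find_peaks", "read_mask", "default_space"]


@dataclass(frozen=True)
class VoxelSpace:
    """Grid dims + affine + boolean mask defining the voxel vector order."""

    shape: tuple[int, int, int]
    affine: np.ndarray
    mask: np.ndarray  # boolean, shape == self.shape

    def __post_init__(self):
        mask = np.asarray(self.mask, dtype=bool)
        if mask.shape != tuple(self.shape):
            raise ValueError(f"mask shape {mask.shape} != grid {self.shape}")
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4) or abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")
        object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "affine", aff)
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def mask_ijk(self) -> np.ndarray:
        """(n_voxels, 3) integer coordinates in flattening order (C order)."""
        return np.argwhere(self.mask)

    def flatten(self, volume: np.ndarray) -> np.ndarray:
        """3-D grid -> in-mask vector (row-major over the grid)."""
        vol = np.asarray(volume)
        if vol.shape != self.shape:
            raise ValueError(f"volume shape {vol.shape} != grid {self.shape}")
        return vol[self.mask]

    def unflatten(self, vector: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """In-mask vector -> 3-D grid with ``fill`` outside the mask."""
        v = np.asarray(vector)
        if v.shape != (self.n_voxels,):
            raise ValueError(f"vector length {v.shape} != {self.n_voxels} mask voxels")
        out = np.full(self.shape, fill, dtype=v.dtype if v.dtype.kind == "f" else float)
        out[self.mask] = v
        return out

    def ijk_to_mm(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        mm = ijk @ self.affine[:3, :3].T + self.affine[:3, 3]
        return mm.squeeze()

    def mm_to_ijk(self, mm: np.ndarray) -> np.ndarray:
        """Nearest voxel index for mm coordinates (rounded)."""
        mm = np.atleast_2d(np.asarray(mm, dtype=float))
        inv = np.linalg.inv(self.affine)
        ijk = mm @ inv[:3, :3].T + inv[:3, 3]
        return np.rint(ijk).astype(int).squeeze()

    def vector_index(self, ijk: tuple[int, int, int]) -> int:
        """Position of a grid voxel within the flattened in-mask vector."""
        if not self.mask[tuple(ijk)]:
            raise ValueError(f"voxel {tuple(ijk)} is outside the mask")
        flat = np.flatnonzero(self.mask.ravel(order="C"))
        lin = np.ravel_multi_index(tuple(ijk), self.shape, order="C")
        return int(np.searchsorted(flat, lin))

    def in_bounds(self, ijk) -> bool:
        return all(0 <= ijk[a] < self.shape[a] for a in range(3))

    # -- NIfTI ---------------------------------------------------------

    def write_map(self, vector: np.ndarray, path: str | Path) -> Path:
        """Write an in-mask vector back through the mask as a NIfTI volume."""
        vol = self.unflatten(np.asarray(vector, dtype=np.float32))
        img = nib.Nifti1Image(vol, self.affine)
        path = Path(path)
        nib.save(img, path)
        return path

    def read_map(self, path: str | Path) -> np.ndarray:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float32)
        return self.flatten(data)

    def write_mask(self, path: str | Path) -> Path:
        img = nib.Nifti1Image(self.mask.astype(np.uint8), self.affine)
        nib.save(img, Path(path))
        return Path(path)


def read_mask(path: str | Path) -> VoxelSpace:
    """Load a binary mask NIfTI as a :class:`VoxelSpace`."""
    img = nib.load(str(path))
    mask = np.asarray(img.dataobj) > 0
    return VoxelSpace(shape=mask.shape, affine=np.asarray(img.affine), mask=mask)


def default_space(shape: tuple[int, int, int] = (12, 12, 12)) -> VoxelSpace:
    """Synthetic analysis space: full-grid mask, 8 mm voxels.

    The affine is chosen so the medial-prefrontal seed coordinates used in
    the connectivity analyses fall inside the grid.
    """
    affine = np.array(
        [
            [8.0, 0, 0, -48.0],
            [0, 8.0, 0, 8.0],
            [0, 0, 8.0, -40.0],
            [0, 0, 0, 1.0],
        ]
    )
    return VoxelSpace(shape=shape, affine=affine, mask=np.ones(shape, dtype=bool))


def find_peaks(
    bsr: np.ndarray,
    space: VoxelSpace,
    threshold: float = 2.58,
    min_separation_mm: float = 10.0,
) -> pd.DataFrame:
    """Local |BSR| maxima above threshold, greedily pruned by separation.

    ``bsr`` is (n_voxels,) or (n_voxels, n_lv).  Within each sign and LV,
    peaks are local maxima of |BSR| over the 26-connected neighborhood,
    sorted by |BSR| descending, and a peak closer than
    ``min_separation_mm`` to an already-kept stronger peak is dropped.
    Returns columns x_mm, y_mm, z_mm, bsr, sign, lv.
    """
    from scipy.ndimage import maximum_filter

    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    b = np.asarray(bsr, dtype=float)
    if b.ndim == 1:
        b = b[:, None]
    rows = []
    for lv in range(b.shape[1]):
        for sign in (+1, -1):
            vec = np.where(np.isfinite(b[:, lv]), sign * b[:, lv], -np.inf)
            vol = space.unflatten(np.where(vec > 0, vec, 0.0), fill=0.0)
            local_max = maximum_filter(vol, size=3, mode="constant") == vol
            cand = np.argwhere(local_max & (vol >= threshold) & space.mask)
            if cand.size == 0:
                continue
            values = vol[tuple(cand.T)]
            order = np.argsort(-values)
            kept_mm: list[np.ndarray] = []
            for idx in order:
                ijk = cand[idx]
                mm = np.atleast_1d(space.ijk_to_mm(ijk))
                if any(
                    np.linalg.norm(mm - k) < min_separation_mm for k in kept_mm
                ):
                    continue
                kept_mm.append(mm)
                rows.append(
                    {
                        "x_mm": float(mm[0]),
                        "y_mm": float(mm[1]),
                        "z_mm": float(mm[2]),
                        "bsr": float(sign * values[idx]),
                        "sign": "+" if sign > 0 else "-",
                        "lv": lv + 1,
                    }
                )
    return pd.DataFrame(rows, columns=["x_mm", "y_mm", "z_mm", "bsr", "sign", "lv"])
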
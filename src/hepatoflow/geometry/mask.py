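"""Voxelized organ domains.

The organ (here: a liver) is represented as a boolean occupancy raster with
isotropic spacing ``h``.  Physical coordinates are cell-centered:
``x = (i + 0.5) * h`` for voxel index ``i``.  An optional per-voxel lobe label
(small positive integer on foreground, 0 on background) supports lobe-wise
pathology definitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class OrganMask:
    """Voxelized organ domain.

    Parameters
    ----------
    spacing : float
        Isotropic voxel edge length in mm.
    occupancy : ndarray of bool, shape (nx, ny, nz)
        Foreground (organ) voxels.
    lobe_label : ndarray of int, same shape
        Positive lobe index on foreground voxels, 0 on background.
    """

    spacing: float
    occupancy: np.ndarray
    lobe_label: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        if self.occupancy.ndim != 3:
            raise ValueError("occupancy must be a 3D array")
        if not self.occupancy.any():
            raise ValueError("mask has no foreground voxels")
        if self.lobe_label is None:
            self.lobe_label = self.occupancy.astype(np.int16)
        self.lobe_label = np.asarray(self.lobe_label)
        if self.lobe_label.shape != self.occupancy.shape:
            raise ValueError("lobe_label shape mismatch")
        if ((self.lobe_label > 0) != self.occupancy).any():
            raise ValueError("lobe_label must be nonzero exactly on foreground")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.occupancy.shape

    @property
    def volume(self) -> float:
        """Organ volume V_liv in mm^3 (foreground count times h^3)."""
        return float(self.occupancy.sum()) * self.spacing**3

    @property
    def n_foreground(self) -> int:
        return int(self.occupancy.sum())

    def voxel_centers(self) -> np.ndarray:
        """Physical centers (mm) of all foreground voxels, shape (n, 3)."""
        idx = np.argwhere(self.occupancy)
        return (idx + 0.5) * self.spacing

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Whether each physical point lies in a foreground voxel."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        idx = np.floor(pts / self.spacing).astype(int)
        ok = np.all((idx >= 0) & (idx < np.array(self.shape)), axis=1)
        out = np.zeros(len(pts), dtype=bool)
        sel = idx[ok]
        out[ok] = self.occupancy[sel[:, 0], sel[:, 1], sel[:, 2]]
        return out if np.asarray(points).ndim > 1 else out[0]

    def distance_to_foreground(self, points: np.ndarray) -> np.ndarray:
        """Distance (mm) from points to the nearest foreground voxel center."""
        centers = self.voxel_centers()
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        from scipy.spatial import cKDTree

        d, _ = cKDTree(centers).query(pts)
        return d if np.asarray(points).ndim > 1 else d[0]


def generate_synthetic_mask(
    half_axes: tuple[float, float, float],
    spacing: float,
    lobe_split_plane: tuple[int, float] = (0, 0.0),
    seed: int = 0,
    margin: int = 1,
) -> OrganMask:
    """Generate an ellipsoidal two-lobe organ mask.

    A stand-in for a CT-derived liver segmentation: an axis-aligned ellipsoid
    with the given half axes (mm), split into two lobes by an axis-aligned
    plane through ``offset`` mm from the ellipsoid center along ``axis``.

    Deterministic for fixed inputs (``seed`` is accepted for interface
    uniformity; the ellipsoid itself involves no randomness).
    """
    ha = np.asarray(half_axes, dtype=float)
    if np.any(ha <= 0) or spacing <= 0:
        raise ValueError("half_axes and spacing must be positive")
    if np.any(spacing > ha):
        raise ValueError(
            "degenerate ellipsoid: spacing exceeds a half axis, no voxel fits"
        )
    n = np.ceil(2 * ha / spacing).astype(int) + 2 * margin
    center = n * spacing / 2.0
    ii = [np.arange(n[k]) * spacing + 0.5 * spacing - center[k] for k in range(3)]
    X, Y, Z = np.meshgrid(*ii, indexing="ij")
    occ = (X / ha[0]) ** 2 + (Y / ha[1]) ** 2 + (Z / ha[2]) ** 2 <= 1.0
    if not occ.any():
        raise ValueError("degenerate ellipsoid smaller than one voxel")
    axis, offset = lobe_split_plane
    coord = (X, Y, Z)[axis]
    lobe = np.where(occ, np.where(coord < offset, 1, 2), 0).astype(np.int16)
    # guard: both lobes must be non-empty, else collapse to a single label
    if not (lobe == 1).any() or not (lobe == 2).any():
        lobe = occ.astype(np.int16)
    return OrganMask(spacing=spacing, occupancy=occ, lobe_label=lobe)


def save_mask_nifti(mask: OrganMask, path: str) -> None:
    """Write the mask (lobe labels) as a NIfTI raster with isotropic spacing."""
    import nibabel as nib

    affine = np.diag([mask.spacing] * 3 + [1.0])
    img = nib.Nifti1Image(mask.lobe_label.astype(np.int16), affine)
    nib.save(img, path)


def save_scalar_nifti(values: np.ndarray, spacing: float, path: str) -> None:
    """Write a scalar voxel field (pressure, |v|, c_total, lipid ratio, ...)
    as a NIfTI raster with the mask's isotropic spacing."""
    import nibabel as nib

    affine = np.diag([spacing] * 3 + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(values, dtype=np.float32), affine), path)


def load_mask_nifti(path: str) -> OrganMask:
    """Read an organ mask from NIfTI; voxel spacing must be isotropic."""
    import nibabel as nib

    img = nib.load(path)
    zooms = img.header.get_zooms()[:3]
    if not np.allclose(zooms, zooms[0], rtol=1e-6):
        raise ValueError(f"anisotropic spacing {zooms} not supported")
    data = np.asarray(img.dataobj).astype(np.int16)
    return OrganMask(spacing=float(zooms[0]), occupancy=data > 0, lobe_label=data)
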
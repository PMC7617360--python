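"""Emission-tomography system model: 2-D parallel-beam projector with image-space PSF.

The system matrix A factorises as A = P·G, where P is a ray-driven parallel-beam
projector (bilinear interpolation along equally spaced sample points, Joseph-style)
stored as a sparse matrix, and G is an isotropic image-space Gaussian modelling the
scanner point-spread function.  The backprojector is the exact adjoint Aᵀ = G·Pᵀ:
Pᵀ is the sparse transpose and G is self-adjoint (symmetric kernel, zero-padded
boundaries), so ⟨Ax, y⟩ = ⟨x, Aᵀy⟩ holds to floating-point precision.

All distances are in millimetres.  Angles cover [0, π) as in a standard sinogram.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
import scipy.sparse as sp

# FWHM = 2*sqrt(2*ln 2) * sigma for a Gaussian
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: voxels whose sensitivity falls below this fraction of the maximum are
#: outside the field of view and excluded from updates and metrics
FOV_SENSITIVITY_FRACTION = 1e-6


class GeometryError(ValueError):
    """Raised for non-positive or inconsistent acquisition geometry."""


@dataclass(frozen=True)
class Geometry:
    """Parallel-beam acquisition geometry for a 2-D image slice.

    Parameters
    ----------
    n_angles : int
        Number of projection angles, equally spaced over [0, π).
    n_bins : int
        Number of radial detector bins per angle.
    bin_spacing_mm : float
        Radial bin width in mm.
    image_shape : tuple of int
        (rows, cols) of the reconstructed image grid.
    voxel_spacing_mm : tuple of float
        Voxel size (row, col) in mm.
    """

    n_angles: int = 60
    n_bins: int = 95
    bin_spacing_mm: float = 2.0
    image_shape: tuple = (64, 64)
    voxel_spacing_mm: tuple = (2.0, 2.0)

    def __post_init__(self):
        if self.n_angles < 1 or self.n_bins < 1:
            raise GeometryError("n_angles and n_bins must be positive")
        if self.bin_spacing_mm <= 0:
            raise GeometryError("bin_spacing_mm must be positive")
        if any(s < 1 for s in self.image_shape) or len(self.image_shape) != 2:
            raise GeometryError("image_shape must be two positive extents")
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise GeometryError("voxel_spacing_mm must be positive")

    @property
    def sinogram_shape(self):
        return (self.n_angles, self.n_bins)

    @property
    def angles_rad(self):
        return np.arange(self.n_angles) * np.pi / self.n_angles

    @property
    def radial_offsets_mm(self):
        return (np.arange(self.n_bins) - (self.n_bins - 1) / 2.0) * self.bin_spacing_mm

    def to_dict(self):
        return {
            "n_angles": int(self.n_angles),
            "n_bins": int(self.n_bins),
            "bin_spacing_mm": float(self.bin_spacing_mm),
            "image_shape": [int(s) for s in self.image_shape],
            "voxel_spacing_mm": [float(s) for s in self.voxel_spacing_mm],
        }

    @classmethod
    def from_dict(cls, d):
        return cls(
            n_angles=d["n_angles"],
            n_bins=d["n_bins"],
            bin_spacing_mm=d["bin_spacing_mm"],
            image_shape=tuple(d["image_shape"]),
            voxel_spacing_mm=tuple(d["voxel_spacing_mm"]),
        )


def gaussian_smooth(image, fwhm_mm, spacing_mm):
    """Isotropic Gaussian smoothing with a unit-sum kernel.

    σ = FWHM / (2√(2 ln 2)) per axis, converted to voxel units by the voxel
    spacing.  ``fwhm_mm = 0`` is the identity.  Boundaries are zero-padded, so
    total intensity is conserved only for interior-supported images.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be nonnegative")
    image = np.asarray(image, dtype=float)
    if fwhm_mm == 0:
        return image.copy()
    spacing = np.broadcast_to(np.asarray(spacing_mm, dtype=float), (image.ndim,))
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / spacing
    return ndi.gaussian_filter(image, sigma=sigma_vox, mode="constant", cval=0.0)


def _ray_matrix(geom: Geometry) -> sp.csr_matrix:
    """Assemble the sparse pure-projection matrix P (line integrals in mm)."""
    nr, nc = geom.image_shape
    dr, dc = geom.voxel_spacing_mm
    # physical extent; rays sampled at half-voxel steps over the image diagonal
    diag = np.hypot(nr * dr, nc * dc)
    step = 0.5 * min(dr, dc)
    n_steps = int(np.ceil(diag / step)) + 1
    t = (np.arange(n_steps) - (n_steps - 1) / 2.0) * step

    offsets = geom.radial_offsets_mm
    rows_acc, cols_acc, vals_acc = [], [], []
    for ia, phi in enumerate(geom.angles_rad):
        # detector (radial) axis u, ray direction v, in (x, y) mm coordinates
        ux, uy = np.cos(phi), np.sin(phi)
        vx, vy = -np.sin(phi), np.cos(phi)
        # sample points for all bins at once: (n_bins, n_steps)
        px = offsets[:, None] * ux + t[None, :] * vx
        py = offsets[:, None] * uy + t[None, :] * vy
        # fractional voxel indices; x -> column, y -> row, image centred at origin
        fc = px / dc + (nc - 1) / 2.0
        fr = py / dr + (nr - 1) / 2.0
        c0 = np.floor(fc).astype(np.int64)
        r0 = np.floor(fr).astype(np.int64)
        wc = fc - c0
        wr = fr - r0
        bin_idx = np.broadcast_to(np.arange(geom.n_bins)[:, None], fc.shape)
        for drow, dcol, w in (
            (0, 0, (1 - wr) * (1 - wc)),
            (0, 1, (1 - wr) * wc),
            (1, 0, wr * (1 - wc)),
            (1, 1, wr * wc),
        ):
            rr = r0 + drow
            cc = c0 + dcol
            ok = (rr >= 0) & (rr < nr) & (cc >= 0) & (cc < nc) & (w > 0)
            rows_acc.append(ia * geom.n_bins + bin_idx[ok])
            cols_acc.append(rr[ok] * nc + cc[ok])
            vals_acc.append(w[ok] * step)
    rows = np.concatenate(rows_acc)
    cols = np.concatenate(cols_acc)
    vals = np.concatenate(vals_acc)
    mat = sp.coo_matrix(
        (vals, (rows, cols)),
        shape=(geom.n_angles * geom.n_bins, nr * nc),
    )
    return mat.tocsr()


@dataclass
class SystemModel:
    """Forward/backprojection pair with image-space Gaussian PSF.

    Attributes
    ----------
    geometry : Geometry
    psf_fwhm_mm : float
        FWHM of the isotropic resolution-modelling kernel; 0 disables it.
    sensitivity : ndarray
        Backprojection of a unit sinogram (the EM normaliser).
    fov_mask : ndarray of bool
        Voxels with non-negligible sensitivity; updates and metrics are
        restricted to this support.
    """

    geometry: Geometry
    psf_fwhm_mm: float
    matrix: sp.csr_matrix = field(repr=False)
    matrix_t: sp.csr_matrix = field(repr=False)
    sensitivity: np.ndarray = field(repr=False)
    fov_mask: np.ndarray = field(repr=False)

    def _smooth(self, image):
        return gaussian_smooth(image, self.psf_fwhm_mm, self.geometry.voxel_spacing_mm)


def build_system(geometry: Geometry, psf_fwhm_mm: float = 0.0) -> SystemModel:
    """Build the system model and precompute its sensitivity image.

    The PSF is applied in image space before projection (A = P·G) and after
    backprojection (Aᵀ = G·Pᵀ); G is symmetric so the pair stays adjoint.
    """
    if psf_fwhm_mm < 0:
        raise GeometryError("psf_fwhm_mm must be nonnegative")
    mat = _ray_matrix(geometry)
    model = SystemModel(
        geometry=geometry,
        psf_fwhm_mm=float(psf_fwhm_mm),
        matrix=mat,
        matrix_t=mat.T.tocsr(),
        sensitivity=np.empty(geometry.image_shape),
        fov_mask=np.empty(geometry.image_shape, dtype=bool),
    )
    ones = np.ones(geometry.sinogram_shape)
    sens = backproject(model, ones)
    model.sensitivity = sens
    model.fov_mask = sens > FOV_SENSITIVITY_FRACTION * sens.max()
    return model


def forward(system: SystemModel, image) -> np.ndarray:
    """Expected sinogram A·θ = P·(G·θ).  Linear; shape-checked."""
    image = np.asarray(image, dtype=float)
    if image.shape != system.geometry.image_shape:
        raise ValueError(
            f"image shape {image.shape} does not match geometry "
            f"{system.geometry.image_shape}"
        )
    smoothed = system._smooth(image)
    out = system.matrix @ smoothed.ravel()
    return out.reshape(system.geometry.sinogram_shape)


def backproject(system: SystemModel, sino_like) -> np.ndarray:
    """Adjoint Aᵀ·y = G·(Pᵀ·y)."""
    sino = np.asarray(sino_like, dtype=float)
    if sino.shape != system.geometry.sinogram_shape:
        raise ValueError(
            f"sinogram shape {sino.shape} does not match geometry "
            f"{system.geometry.sinogram_shape}"
        )
    img = (system.matrix_t @ sino.ravel()).reshape(system.geometry.image_shape)
    return system._smooth(img)
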
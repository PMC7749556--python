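"""Diffusion tensor estimation, eigenstructure, FA maps, and interpolation.

Per voxel the diffusion-weighted signal follows the mono-exponential tensor
model ``S = S0 * exp(-b g' D g)`` with ``D`` a symmetric positive 3x3 tensor
(units mm^2/s).  Taking logs makes the model linear in the 7 parameters
(ln S0 plus the 6 unique tensor components), so the fit is an ordinary
least-squares solve per voxel.

Tensors are stored as 6 unique components in the order
``(Dxx, Dyy, Dzz, Dxy, Dxz, Dyz)``.

Geometry convention (pinned so tracking is reproducible): voxel indices are
0-based, the world position of voxel ``(i, j, k)`` is ``affine @ (i, j, k, 1)``,
and interpolation is trilinear over the 8 nearest voxel centers; the valid
interpolation domain is the convex hull of voxel centers (continuous voxel
coordinates in ``[0, n-1]`` per axis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TensorField",
    "ScalarMap",
    "OutOfBoundsError",
    "design_matrix",
    "fit_tensor",
    "eigen_decompose",
    "compute_fa",
    "compute_md",
    "fa_map",
    "interpolate_tensor",
    "interpolate_scalar",
]

# floor applied to nonpositive signals before the log-linear fit
SIGNAL_FLOOR = 1e-10

# index pairs of the 6 stored components within the full 3x3 matrix
_COMP_IDX = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]


class OutOfBoundsError(ValueError):
    """A world point fell outside the convex hull of voxel centers."""


def _default_affine(voxel_size: float | tuple) -> np.ndarray:
    vs = np.atleast_1d(np.asarray(voxel_size, dtype=float))
    if vs.size == 1:
        vs = np.repeat(vs, 3)
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = vs
    return aff


@dataclass
class TensorField:
    """Grid of symmetric diffusion tensors.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz, 6)
        Unique tensor components ``(Dxx, Dyy, Dzz, Dxy, Dxz, Dyz)`` in mm^2/s.
    voxel_size : float or 3-tuple
        Edge length(s) of a voxel in mm.
    affine : ndarray (4, 4), optional
        Grid-to-world transform; defaults to a scaling by ``voxel_size``.
    mask : ndarray (nx, ny, nz) of bool, optional
        Voxels with a valid fit.  Defaults to all True.
    """

    data: np.ndarray
    voxel_size: float | tuple = 2.5
    affine: np.ndarray | None = None
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4 or self.data.shape[-1] != 6:
            raise ValueError(f"tensor data must have shape (nx, ny, nz, 6), got {self.data.shape}")
        if np.min(np.atleast_1d(self.voxel_size)) <= 0:
            raise ValueError("voxel size must be positive")
        if self.affine is None:
            self.affine = _default_affine(self.voxel_size)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.mask is None:
            self.mask = np.ones(self.data.shape[:3], dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def shape(self) -> tuple:
        return self.data.shape[:3]

    def as_matrices(self) -> np.ndarray:
        """Expand to full symmetric matrices, shape (nx, ny, nz, 3, 3)."""
        return components_to_matrices(self.data)

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]


@dataclass
class ScalarMap:
    """3D scalar map (e.g. FA) sharing geometry with its TensorField."""

    data: np.ndarray
    voxel_size: float | tuple = 2.5
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"scalar map must be 3D, got shape {self.data.shape}")
        if self.affine is None:
            self.affine = _default_affine(self.voxel_size)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple:
        return self.data.shape


def components_to_matrices(comp: np.ndarray) -> np.ndarray:
    comp = np.asarray(comp, dtype=float)
    out = np.zeros(comp.shape[:-1] + (3, 3))
    for c, (i, j) in enumerate(_COMP_IDX):
        out[..., i, j] = comp[..., c]
        out[..., j, i] = comp[..., c]
    return out


def matrices_to_components(mat: np.ndarray) -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    out = np.empty(mat.shape[:-2] + (6,))
    for c, (i, j) in enumerate(_COMP_IDX):
        out[..., c] = mat[..., i, j]
    return out


# ---------------------------------------------------------------------------
# Log-linear tensor fit
# ---------------------------------------------------------------------------

def design_matrix(scheme) -> np.ndarray:
    """Design matrix of the log-linear model, shape (n_volumes, 7).

    Columns multiply ``(ln S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz)``; the quadratic
    form ``g' D g`` expands the off-diagonal components with a factor 2.
    """
    b = np.asarray(scheme.bvals, dtype=float)
    g = np.asarray(scheme.bvecs, dtype=float)
    gx, gy, gz = g[:, 0], g[:, 1], g[:, 2]
    return np.column_stack(
        [
            np.ones_like(b),
            -b * gx * gx,
            -b * gy * gy,
            -b * gz * gz,
            -2.0 * b * gx * gy,
            -2.0 * b * gx * gz,
            -2.0 * b * gy * gz,
        ]
    )


def fit_tensor(dwi: np.ndarray, scheme, mask: np.ndarray | None = None) -> TensorField:
    """Fit a diffusion tensor per voxel by ordinary least squares on log signals.

    Parameters
    ----------
    dwi : ndarray, shape (nx, ny, nz, n_volumes)
        Diffusion-weighted magnitude data.
    scheme : GradientScheme
        Must contain at least 6 noncollinear weighted directions and a b=0
        entry, and as many entries as DWI volumes.
    mask : ndarray of bool, optional
        Restrict fitting to these voxels; outside voxels carry zero tensors.

    Returns
    -------
    TensorField
        With ``mask`` marking the voxels actually fitted (the input mask
        minus voxels whose signal is everywhere nonpositive).
    """
    dwi = np.asarray(dwi, dtype=float)
    if dwi.ndim != 4:
        raise ValueError(f"dwi must be 4D, got shape {dwi.shape}")
    n_vol = len(scheme.bvals)
    if dwi.shape[-1] != n_vol:
        raise ValueError(
            f"volume count mismatch: dwi has {dwi.shape[-1]} volumes, scheme has {n_vol} entries"
        )
    A = design_matrix(scheme)
    if np.linalg.matrix_rank(A) < 7:
        raise ValueError(
            "gradient scheme design matrix is rank deficient; "
            "at least 6 noncollinear weighted directions plus b=0 are required"
        )

    shape = dwi.shape[:3]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    # all-zero (or negative) signal voxels cannot be fitted; drop them quietly
    fit_mask = mask & (dwi.max(axis=-1) > 0)

    comps = np.zeros(shape + (6,))
    vox = dwi[fit_mask]  # (n_fit, n_vol)
    if vox.size:
        logs = np.log(np.clip(vox, SIGNAL_FLOOR, None))
        coef, *_ = np.linalg.lstsq(A, logs.T, rcond=None)
        comps[fit_mask] = coef[1:].T
    try:
        voxel_size = scheme.voxel_size  # optional attribute
    except AttributeError:
        voxel_size = 2.5
    return TensorField(comps, voxel_size=voxel_size, mask=fit_mask)


# ---------------------------------------------------------------------------
# Eigenstructure and FA
# ---------------------------------------------------------------------------

def eigen_decompose(field: TensorField | np.ndarray):
    """Eigenvalues (descending) and eigenvectors of every voxel tensor.

    Returns
    -------
    evals : ndarray (..., 3)
        Sorted descending, ``lam1 >= lam2 >= lam3``.
    evecs : ndarray (..., 3, 3)
        ``evecs[..., :, k]`` is the unit eigenvector of ``evals[..., k]``.
        Sign fixed by making each eigenvector's largest-magnitude component
        positive, so output is deterministic.
    """
    if isinstance(field, TensorField):
        mats = field.as_matrices()
    else:
        mats = components_to_matrices(np.asarray(field)) if np.asarray(field).shape[-1] == 6 else np.asarray(field, dtype=float)
    evals, evecs = np.linalg.eigh(mats)  # ascending
    evals = evals[..., ::-1]
    evecs = evecs[..., ::-1]
    # deterministic sign: largest |component| of each eigenvector positive
    comp_idx = np.argmax(np.abs(evecs), axis=-2, keepdims=True)
    signs = np.sign(np.take_along_axis(evecs, comp_idx, axis=-2))
    signs[signs == 0] = 1.0
    evecs = evecs * signs
    return evals, evecs


def compute_fa(lam1, lam2=None, lam3=None) -> np.ndarray:
    """Fractional anisotropy from eigenvalue maps.

    FA = sqrt(1/2) * sqrt((l1-l2)^2 + (l2-l3)^2 + (l1-l3)^2) / sqrt(l1^2+l2^2+l3^2)

    Negative eigenvalues (noise artifacts) are clamped to 0 first; a voxel
    whose eigenvalues are all zero gets FA = 0 (background convention).
    Accepts either three separate maps or a single (..., 3) stack.
    """
    if lam2 is None:
        lam = np.asarray(lam1, dtype=float)
    else:
        lam = np.stack([np.asarray(lam1, dtype=float),
                        np.asarray(lam2, dtype=float),
                        np.asarray(lam3, dtype=float)], axis=-1)
    lam = np.clip(lam, 0.0, None)
    l1, l2, l3 = lam[..., 0], lam[..., 1], lam[..., 2]
    num = np.sqrt(0.5) * np.sqrt((l1 - l2) ** 2 + (l2 - l3) ** 2 + (l1 - l3) ** 2)
    den = np.sqrt(l1 ** 2 + l2 ** 2 + l3 ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return np.clip(fa, 0.0, 1.0)


def compute_md(lam1, lam2=None, lam3=None) -> np.ndarray:
    """Mean diffusivity (lam1 + lam2 + lam3) / 3 in mm^2/s."""
    if lam2 is None:
        lam = np.asarray(lam1, dtype=float)
        return lam.mean(axis=-1)
    return (np.asarray(lam1) + np.asarray(lam2) + np.asarray(lam3)) / 3.0


def fa_map(field: TensorField) -> ScalarMap:
    """FA ScalarMap of a TensorField (masked-out voxels get FA = 0)."""
    evals, _ = eigen_decompose(field)
    fa = compute_fa(evals)
    fa[~field.mask] = 0.0
    return ScalarMap(fa, voxel_size=field.voxel_size, affine=field.affine)


# ---------------------------------------------------------------------------
# Trilinear interpolation in world coordinates
# ---------------------------------------------------------------------------

def _voxel_coords(affine: np.ndarray, point) -> np.ndarray:
    point = np.asarray(point, dtype=float)
    inv = np.linalg.inv(affine)
    return inv[:3, :3] @ point + inv[:3, 3]


def _trilinear(data: np.ndarray, affine: np.ndarray, point) -> np.ndarray:
    """Trilinear interpolation of (nx, ny, nz[, k]) data at a world point."""
    c = _voxel_coords(affine, point)
    shape = np.asarray(data.shape[:3])
    eps = 1e-9
    if np.any(c < -eps) or np.any(c > shape - 1 + eps):
        raise OutOfBoundsError(
            f"point {np.asarray(point).tolist()} (voxel coords {c.tolist()}) is outside "
            f"the interpolation hull of the {tuple(shape)} grid"
        )
    c = np.clip(c, 0.0, shape - 1)
    i0 = np.minimum(np.floor(c).astype(int), shape - 2)
    i0 = np.maximum(i0, 0)
    f = c - i0
    x0, y0, z0 = i0
    block = data[x0:x0 + 2, y0:y0 + 2, z0:z0 + 2]
    wx = np.array([1 - f[0], f[0]])
    wy = np.array([1 - f[1], f[1]])
    wz = np.array([1 - f[2], f[2]])
    w = wx[:, None, None] * wy[None, :, None] * wz[None, None, :]
    if block.ndim == 4:
        return np.tensordot(w, block, axes=([0, 1, 2], [0, 1, 2]))
    return float(np.sum(w * block))


def interpolate_tensor(field: TensorField, point) -> np.ndarray:
    """Trilinearly interpolated 3x3 tensor at a world coordinate (mm).

    Applied component-wise over the 8 surrounding voxel centers; at a voxel
    center this returns that voxel's tensor exactly.  Raises
    :class:`OutOfBoundsError` outside the hull of voxel centers.
    """
    comp = _trilinear(field.data, field.affine, point)
    return components_to_matrices(comp)


def interpolate_scalar(scalar_map: ScalarMap, point) -> float:
    """Trilinearly interpolated scalar value at a world coordinate (mm)."""
    return float(_trilinear(scalar_map.data, scalar_map.affine, point))
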
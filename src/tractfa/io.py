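"""File I/O: NIfTI volumes, FSL-style gradient tables, streamline files, config.

Every pipeline stage reads and writes standard formats so stages can run
standalone: 4D DWI and 3D label/scalar volumes as NIfTI-1, gradient tables
as FSL bval/bvec text files, streamlines as TRK or TCK (selected by file
extension), tensor fields as 4D NIfTI with 6 component volumes plus a mask,
and cohort tables as CSV.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .synthetic import GradientScheme
from .tensor import ScalarMap, TensorField
from .tracking import Streamline, TractBundle

__all__ = [
    "PipelineConfig",
    "read_dwi",
    "write_dwi",
    "read_nifti",
    "write_nifti",
    "read_tensor_field",
    "write_tensor_field",
    "read_streamlines",
    "write_streamlines",
    "provenance",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# NIfTI volumes
# ---------------------------------------------------------------------------

def write_nifti(path, data: np.ndarray, affine: np.ndarray | None = None) -> Path:
    path = Path(path)
    if affine is None:
        affine = np.eye(4)
    img = nib.Nifti1Image(np.asarray(data), np.asarray(affine, dtype=float))
    nib.save(img, str(path))
    return path


def read_nifti(path):
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


# ---------------------------------------------------------------------------
# DWI + FSL gradient table
# ---------------------------------------------------------------------------

def write_dwi(nifti_path, data: np.ndarray, affine: np.ndarray,
              scheme: GradientScheme, bval_path=None, bvec_path=None) -> tuple:
    """Write a 4D DWI volume plus bval/bvec text files.

    The gradient table uses the FSL text dialect: bvals on one
    whitespace-separated line, bvecs as 3 lines (x, y, z components), one
    column per volume.
    """
    nifti_path = Path(nifti_path)
    if data.ndim != 4:
        raise ValueError(f"DWI data must be 4D, got shape {data.shape}")
    if data.shape[-1] != len(scheme):
        raise ValueError(
            f"volume count mismatch: data has {data.shape[-1]} volumes, scheme has {len(scheme)}"
        )
    stem = nifti_path.name
    for suf in (".nii.gz", ".nii"):
        if stem.endswith(suf):
            stem = stem[: -len(suf)]
            break
    bval_path = Path(bval_path) if bval_path else nifti_path.parent / f"{stem}.bval"
    bvec_path = Path(bvec_path) if bvec_path else nifti_path.parent / f"{stem}.bvec"
    write_nifti(nifti_path, data, affine)
    bval_path.write_text(" ".join(f"{b:g}" for b in scheme.bvals) + "\n")
    lines = [" ".join(f"{v:.10g}" for v in scheme.bvecs[:, ax]) for ax in range(3)]
    bvec_path.write_text("\n".join(lines) + "\n")
    return nifti_path, bval_path, bvec_path


def read_dwi(nifti_path, bval_path, bvec_path):
    """Read a 4D DWI volume and its FSL-style gradient table.

    Returns (data, affine, GradientScheme).  Weighted directions that are
    not unit norm are normalised with a logged warning; a volume-count
    mismatch between image and gradient table is rejected naming both
    counts.
    """
    data, affine = read_nifti(nifti_path)
    if data.ndim != 4:
        raise ValueError(f"expected 4D DWI, got shape {data.shape}")
    bvals = np.loadtxt(str(bval_path), dtype=float).ravel()
    bvecs = np.loadtxt(str(bvec_path), dtype=float)
    if bvecs.shape[0] != 3:
        if bvecs.shape[1] == 3:
            bvecs = bvecs.T
        else:
            raise ValueError(f"bvec file must have 3 rows of components, got shape {bvecs.shape}")
    bvecs = bvecs.T  # (n, 3)
    if len(bvals) != data.shape[-1] or len(bvecs) != data.shape[-1]:
        raise ValueError(
            f"gradient count mismatch: image has {data.shape[-1]} volumes, "
            f"bval has {len(bvals)}, bvec has {len(bvecs)} entries"
        )
    weighted = bvals > 0
    norms = np.linalg.norm(bvecs[weighted], axis=1)
    off = np.abs(norms - 1.0) > 1e-6
    if np.any(off):
        logger.warning("normalising %d non-unit gradient direction(s)", int(off.sum()))
        bvecs[weighted] = bvecs[weighted] / norms[:, None]
    voxel_size = float(np.abs(affine[0, 0])) if affine[0, 0] != 0 else 2.5
    scheme = GradientScheme(bvals, bvecs, voxel_size=voxel_size)
    return data, affine, scheme


# ---------------------------------------------------------------------------
# Tensor fields
# ---------------------------------------------------------------------------

def write_tensor_field(field: TensorField, path) -> tuple:
    """Write a tensor field as a 4D NIfTI (6 component volumes) plus a mask."""
    path = Path(path)
    stem = path.name
    for suf in (".nii.gz", ".nii"):
        if stem.endswith(suf):
            stem = stem[: -len(suf)]
            break
    mask_path = path.parent / f"{stem}_mask.nii"
    write_nifti(path, field.data, field.affine)
    write_nifti(mask_path, field.mask.astype(np.uint8), field.affine)
    return path, mask_path


def read_tensor_field(path, mask_path=None) -> TensorField:
    data, affine = read_nifti(path)
    if data.ndim != 4 or data.shape[-1] != 6:
        raise ValueError(f"tensor field file must be (nx, ny, nz, 6), got {data.shape}")
    mask = None
    if mask_path is not None and Path(mask_path).exists():
        mask = read_nifti(mask_path)[0].astype(bool)
    voxel_size = tuple(np.abs(np.diag(affine)[:3]))
    return TensorField(data, voxel_size=voxel_size, affine=affine, mask=mask)


# ---------------------------------------------------------------------------
# Streamlines (TRK / TCK)
# ---------------------------------------------------------------------------

def write_streamlines(bundles, path, reference: TensorField | ScalarMap | None = None) -> Path:
    """Write streamlines to a TRK or TCK file (selected by extension).

    Points are stored in world (RAS mm) coordinates; the per-point FA is
    stored as a 'fa' data_per_point attribute where the format allows it
    (TRK; the TCK format cannot carry per-point scalars and drops them with
    a warning).  ``reference`` supplies the voxel grid for the TRK header;
    identity geometry is used when absent.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix not in (".trk", ".tck"):
        raise ValueError(f"unknown streamline format {suffix!r}; supported: .trk, .tck")
    if isinstance(bundles, TractBundle):
        bundles = [bundles]
    lines = [np.asarray(s.points, dtype=np.float32)
             for b in bundles for s in b.streamlines]
    fa = [np.asarray(s.fa, dtype=np.float32)[:, None]
          for b in bundles for s in b.streamlines]
    tractogram = nib.streamlines.Tractogram(
        lines, data_per_point={"fa": fa}, affine_to_rasmm=np.eye(4))
    if suffix == ".trk":
        header = {}
        if reference is not None:
            header["voxel_to_rasmm"] = np.asarray(reference.affine, dtype=np.float32)
            header["voxel_sizes"] = np.abs(np.diag(reference.affine)[:3]).astype(np.float32)
            header["dimensions"] = np.asarray(reference.shape[:3], dtype=np.int16)
        f = nib.streamlines.TrkFile(tractogram, header=header)
    else:
        f = nib.streamlines.TckFile(tractogram)
    f.save(str(path))
    return path


def read_streamlines(path) -> list:
    """Read a TRK/TCK file back into Streamline objects (world mm points)."""
    path = Path(path)
    if path.suffix.lower() not in (".trk", ".tck"):
        raise ValueError(f"unknown streamline format {path.suffix!r}; supported: .trk, .tck")
    tf = nib.streamlines.load(str(path))
    tractogram = tf.tractogram.to_world()
    out = []
    for i, pts in enumerate(tractogram.streamlines):
        if "fa" in tractogram.data_per_point:
            fa = np.asarray(tractogram.data_per_point["fa"][i]).ravel()
        else:
            fa = np.zeros(len(pts))
        out.append(Streamline(np.asarray(pts, dtype=float), fa))
    return out


# ---------------------------------------------------------------------------
# Pipeline configuration and provenance
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """End-to-end pipeline settings; defaults reproduce the study protocol.

    30 directions at b=1000 s/mm^2 + 1 b=0, 2.5 mm voxels, 0.5 mm tracking
    step, FA < 0.25 and turning angle > 45 degrees termination, ANCOVA with
    the four clinical covariates, family threshold .001 (paper mode),
    pooled-variance t tests.
    """

    n_dirs: int = 30
    b_value: float = 1000.0
    n_b0: int = 1
    voxel_size: float = 2.5
    step: float = 0.5
    fa_threshold: float = 0.25
    max_angle_deg: float = 45.0
    seeds_per_voxel: int = 1
    n_per_group: int = 30
    family_mode: str = "paper"      # 'paper' (.001) or 'exact' (alpha/n)
    alpha: float = 0.05
    t_variant: str = "pooled"       # or 'welch'
    fa_mean_method: str = "pooled"  # or 'per-fiber'
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=False))
        return path


def provenance(config: PipelineConfig | None = None, seed: int | None = None) -> dict:
    """Provenance block written next to every CLI output."""
    import scipy

    from . import __version__

    block = {
        "tractfa": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "nibabel": nib.__version__,
        "python": platform.python_version(),
    }
    if config is not None:
        block["config"] = asdict(config)
    if seed is not None:
        block["seed"] = int(seed)
    return block


def write_provenance(path, config=None, seed=None) -> Path:
    path = Path(path)
    path.write_text(json.dumps(provenance(config, seed), indent=2, sort_keys=True) + "\n")
    return path
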
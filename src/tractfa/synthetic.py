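"""Synthetic DWI phantoms and cohort tables.

This module generates every input the pipeline needs so that tensor fitting,
tractography and the group statistics can be exercised with known ground
truth:

* diffusion gradient schemes (noncollinear unit directions at a single shell
  plus b=0 baselines), spread over the sphere by electrostatic repulsion
  with antipodal symmetry;
* tensor-field phantoms built from tube-shaped fiber bundles (straight or
  circular-arc centerlines) with analytic tangents, embedded in an isotropic
  background, together with a parcel-label volume marking each bundle;
* the DWI forward model ``S = S0 exp(-b g' D g)`` with Rician noise
  (magnitude of a complex Gaussian perturbation);
* cohort tables for three groups (HC, MDD, BD) with per-tract mean-FA
  columns, demographic/clinical covariates, cognition scores, and an exactly
  calibrated Pearson correlation between one tract's FA and one score within
  one group.

Defaults follow a clinical 3T protocol: 30 directions at b = 1000 s/mm^2,
one b=0 volume, 2.5 mm isotropic voxels, and an SNR of 30 (sigma = S0/30).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as _field

import numpy as np
import pandas as pd

from .tensor import TensorField, matrices_to_components

__all__ = [
    "GradientScheme",
    "BundleSpec",
    "PhantomSpec",
    "CohortSpec",
    "GroupParams",
    "JHU_TRACTS_54",
    "GROUPS",
    "make_gradient_scheme",
    "make_phantom",
    "simulate_dwi",
    "make_cohort",
]

GROUPS = ("HC", "MDD", "BD")

# 27 bilateral white-matter structures, named after the JHU DTI atlas
# conventions, giving the 54 seed parcels used throughout.
_JHU_BASE = [
    "middle_cerebellar_peduncle", "genu_cc", "body_cc", "splenium_cc",
    "fornix", "corticospinal_tract", "medial_lemniscus",
    "inferior_cerebellar_peduncle", "superior_cerebellar_peduncle",
    "cerebral_peduncle", "anterior_limb_ic", "posterior_limb_ic",
    "retrolenticular_ic", "anterior_corona_radiata",
    "superior_corona_radiata", "posterior_corona_radiata",
    "posterior_thalamic_radiation", "sagittal_stratum", "external_capsule",
    "cingulum_cingulate", "cingulum_hippocampal", "fornix_stria_terminalis",
    "superior_longitudinal_fasciculus", "superior_fronto_occipital_fasciculus",
    "inferior_fronto_occipital_fasciculus", "uncinate_fasciculus", "tapetum",
]
JHU_TRACTS_54 = tuple(f"{b}_{side}" for b in _JHU_BASE for side in ("L", "R"))


# ---------------------------------------------------------------------------
# Gradient scheme
# ---------------------------------------------------------------------------

@dataclass
class GradientScheme:
    """Diffusion encoding: one b-value and one direction per volume.

    b=0 entries carry a zero direction vector; every weighted direction has
    unit Euclidean norm.  Shared between simulation and fitting so the two
    always agree on the encoding.
    """

    bvals: np.ndarray
    bvecs: np.ndarray
    voxel_size: float = 2.5

    def __post_init__(self) -> None:
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float).reshape(-1, 3)
        self.validate()

    def validate(self) -> None:
        if len(self.bvals) != len(self.bvecs):
            raise ValueError(
                f"bvals ({len(self.bvals)}) and bvecs ({len(self.bvecs)}) lengths differ"
            )
        weighted = self.bvals > 0
        norms = np.linalg.norm(self.bvecs[weighted], axis=1)
        if norms.size and np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("every weighted (b>0) direction must have unit norm")
        if int(np.sum(~weighted)) < 1:
            raise ValueError("at least one b=0 entry is required")
        if int(np.sum(weighted)) < 6:
            raise ValueError(
                "at least 6 noncollinear weighted directions are required for a tensor fit"
            )

    def __len__(self) -> int:
        return len(self.bvals)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    @property
    def n_directions(self) -> int:
        return int(np.sum(self.bvals > 0))


def _repulsion_directions(n: int, seed: int, n_iter: int = 600) -> np.ndarray:
    """Spread n unit vectors over the sphere by electrostatic repulsion.

    Antipodal symmetry: each point repels both the other points and their
    antipodes (diffusion directions are sign-invariant).  Deterministic for
    a fixed seed: seeded random start, fixed-schedule projected gradient
    descent on the Coulomb potential.
    """
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, 3))
    x /= np.linalg.norm(x, axis=1, keepdims=True)
    step = 0.1
    for it in range(n_iter):
        d_plus = x[:, None, :] - x[None, :, :]   # xi - xj
        d_minus = x[:, None, :] + x[None, :, :]  # xi - (-xj)
        r_plus = np.linalg.norm(d_plus, axis=-1)
        r_minus = np.linalg.norm(d_minus, axis=-1)
        np.fill_diagonal(r_plus, np.inf)
        # xi + xi has norm 2: a constant self-term, harmless but excluded
        np.fill_diagonal(r_minus, np.inf)
        force = (d_plus / r_plus[..., None] ** 3).sum(axis=1)
        force += (d_minus / r_minus[..., None] ** 3).sum(axis=1)
        # tangential component only, then re-project onto the sphere
        force -= (np.sum(force * x, axis=1, keepdims=True)) * x
        norm = np.linalg.norm(force, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        x = x + step * force / norm
        x /= np.linalg.norm(x, axis=1, keepdims=True)
        step *= 0.99
    return x


def make_gradient_scheme(n_dirs: int, b: float = 1000.0, n_b0: int = 1,
                         seed: int = 0) -> GradientScheme:
    """Build a single-shell gradient scheme with well-spread directions.

    Parameters
    ----------
    n_dirs : int
        Number of weighted directions (>= 6 for tensor determinacy).
    b : float
        Shell b-value in s/mm^2.
    n_b0 : int
        Number of unweighted (b=0) baseline volumes, listed first.
    seed : int
        Seed for the repulsion initialisation; output is deterministic.
    """
    if n_dirs < 6:
        raise ValueError(f"n_dirs must be >= 6 (tensor fit is under-determined), got {n_dirs}")
    if n_b0 < 1:
        raise ValueError("at least one b=0 volume is required")
    dirs = _repulsion_directions(n_dirs, seed)
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_dirs, float(b))])
    bvecs = np.vstack([np.zeros((n_b0, 3)), dirs])
    return GradientScheme(bvals, bvecs)


# ---------------------------------------------------------------------------
# Phantom geometry
# ---------------------------------------------------------------------------

@dataclass
class BundleSpec:
    """One tube-shaped fiber bundle with an analytic centerline.

    kind="straight": centerline ``start + t*direction`` for t in [0, length].
    kind="arc": circular arc ``center + R*(cos(t) u + sin(t) v)`` for t in
    [theta0, theta1]; ``u`` and ``v`` are orthonormalised in-plane axes and
    R is ``arc_radius``.  Tangents are analytic, which gives tractography an
    exact ground-truth trajectory.
    """

    kind: str
    label: int
    radius: float                      # tube radius, mm
    evals: tuple = (1.7e-3, 0.3e-3, 0.2e-3)   # mm^2/s, lam1 >= lam2 >= lam3
    # straight
    start: tuple = (0.0, 0.0, 0.0)
    direction: tuple = (1.0, 0.0, 0.0)
    length: float = 0.0
    # arc
    center: tuple = (0.0, 0.0, 0.0)
    arc_radius: float = 0.0
    plane_u: tuple = (1.0, 0.0, 0.0)
    plane_v: tuple = (0.0, 1.0, 0.0)
    theta_range: tuple = (0.0, math.pi / 2)

    def validate(self, voxel_size: float) -> None:
        l1, l2, l3 = self.evals
        if not (l1 >= l2 >= l3 > 0):
            raise ValueError(f"bundle eigenvalues must satisfy lam1 >= lam2 >= lam3 > 0, got {self.evals}")
        if self.radius <= voxel_size / 2:
            raise ValueError(f"bundle radius {self.radius} mm must exceed half a voxel ({voxel_size / 2} mm)")
        if not (isinstance(self.label, (int, np.integer)) and 0 < self.label <= 54):
            raise ValueError(f"parcel label must be a positive integer <= 54, got {self.label}")
        if self.kind not in ("straight", "arc"):
            raise ValueError(f"unknown bundle kind {self.kind!r}")

    def centerline_frame(self, points: np.ndarray):
        """(distance to centerline, unit tangent) for an array of world points."""
        p = np.asarray(points, dtype=float)
        if self.kind == "straight":
            d = np.asarray(self.direction, dtype=float)
            d = d / np.linalg.norm(d)
            rel = p - np.asarray(self.start, dtype=float)
            t = rel @ d
            t = np.clip(t, 0.0, self.length)
            nearest = np.asarray(self.start) + t[..., None] * d
            dist = np.linalg.norm(p - nearest, axis=-1)
            tang = np.broadcast_to(d, p.shape).copy()
            return dist, tang
        # arc
        u = np.asarray(self.plane_u, dtype=float)
        u = u / np.linalg.norm(u)
        v = np.asarray(self.plane_v, dtype=float)
        v = v - (v @ u) * u
        v = v / np.linalg.norm(v)
        c = np.asarray(self.center, dtype=float)
        rel = p - c
        a = rel @ u
        bb = rel @ v
        theta = np.arctan2(bb, a)
        t0, t1 = self.theta_range
        theta = np.clip(theta, t0, t1)
        nearest = c + self.arc_radius * (np.cos(theta)[..., None] * u + np.sin(theta)[..., None] * v)
        dist = np.linalg.norm(p - nearest, axis=-1)
        tang = -np.sin(theta)[..., None] * u + np.cos(theta)[..., None] * v
        return dist, tang


@dataclass
class PhantomSpec:
    """Geometry and signal parameters of a synthetic DWI phantom."""

    shape: tuple = (40, 40, 12)
    voxel_size: float = 2.5
    bundles: list = _field(default_factory=list)
    background_evals: tuple = (0.7e-3, 0.7e-3, 0.7e-3)
    S0: float = 1000.0
    sigma: float | None = None      # None -> S0/30 (SNR 30)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma is None:
            self.sigma = self.S0 / 30.0
        l1, l2, l3 = self.background_evals
        if not (l1 >= l2 >= l3 > 0):
            raise ValueError("background eigenvalues must satisfy lam1 >= lam2 >= lam3 > 0")
        labels = [b.label for b in self.bundles]
        if len(set(labels)) != len(labels):
            raise ValueError(f"bundle parcel labels must be distinct, got {labels}")
        for b in self.bundles:
            b.validate(self.voxel_size)


def _tangent_tensor(tangents: np.ndarray, evals) -> np.ndarray:
    """Tensors with lam1 along each tangent (lam2/lam3 axes arbitrary but fixed)."""
    l1, l2, l3 = evals
    e1 = tangents / np.linalg.norm(tangents, axis=-1, keepdims=True)
    # a reference vector never parallel to e1
    ref = np.zeros_like(e1)
    ref[..., 2] = 1.0
    close = np.abs(e1[..., 2]) > 0.9
    ref[close] = np.array([0.0, 1.0, 0.0])
    e2 = np.cross(e1, ref)
    e2 /= np.linalg.norm(e2, axis=-1, keepdims=True)
    e3 = np.cross(e1, e2)
    D = (l1 * e1[..., :, None] * e1[..., None, :]
         + l2 * e2[..., :, None] * e2[..., None, :]
         + l3 * e3[..., :, None] * e3[..., None, :])
    return D


def make_phantom(spec: PhantomSpec):
    """Build the ground-truth tensor field and parcel-label volume.

    Voxels whose centers fall inside a bundle's tube get the bundle's
    eigenvalues with the principal axis along the local centerline tangent;
    all other voxels get the isotropic background tensor.  The label volume
    carries the bundle's parcel id inside the tube and 0 elsewhere.

    Raises
    ------
    ValueError
        If two bundles claim the same voxel (conflicting labels).
    """
    nx, ny, nz = spec.shape
    idx = np.stack(np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                               indexing="ij"), axis=-1).astype(float)
    centers = idx * spec.voxel_size  # world coords of voxel centers

    bg = np.diag(spec.background_evals)
    D = np.broadcast_to(bg, (nx, ny, nz, 3, 3)).copy()
    labels = np.zeros((nx, ny, nz), dtype=int)

    for bundle in spec.bundles:
        dist, tang = bundle.centerline_frame(centers)
        inside = dist <= bundle.radius
        conflict = inside & (labels != 0)
        if np.any(conflict):
            other = int(labels[conflict][0])
            raise ValueError(
                f"bundles overlap with conflicting labels: parcel {bundle.label} "
                f"claims voxels already labelled {other}"
            )
        D[inside] = _tangent_tensor(tang[inside], bundle.evals)
        labels[inside] = bundle.label

    field = TensorField(matrices_to_components(D), voxel_size=spec.voxel_size)
    return field, labels


# ---------------------------------------------------------------------------
# DWI forward model with Rician noise
# ---------------------------------------------------------------------------

def simulate_dwi(field: TensorField, scheme: GradientScheme, S0: float = 1000.0,
                 sigma: float = 0.0, seed: int = 0) -> np.ndarray:
    """Simulate a 4D DWI volume from a tensor field.

    Noiseless signal per voxel and encoding entry: ``S = S0 exp(-b g' D g)``.
    Rician noise is applied as ``sqrt((S + e1)^2 + e2^2)`` with independent
    ``e1, e2 ~ Normal(0, sigma^2)`` — the magnitude of a complex Gaussian
    perturbation, the standard model for magnitude MRI.  ``sigma = 0``
    reproduces the noiseless forward model exactly.
    """
    if sigma < 0:
        raise ValueError("noise sigma must be >= 0")
    b = np.asarray(scheme.bvals, dtype=float)
    g = np.asarray(scheme.bvecs, dtype=float)
    comp = field.data  # (nx, ny, nz, 6): Dxx Dyy Dzz Dxy Dxz Dyz
    gx, gy, gz = g[:, 0], g[:, 1], g[:, 2]
    # g' D g expanded over the 6 unique components
    quad = (np.multiply.outer(comp[..., 0], gx * gx)
            + np.multiply.outer(comp[..., 1], gy * gy)
            + np.multiply.outer(comp[..., 2], gz * gz)
            + 2.0 * np.multiply.outer(comp[..., 3], gx * gy)
            + 2.0 * np.multiply.outer(comp[..., 4], gx * gz)
            + 2.0 * np.multiply.outer(comp[..., 5], gy * gz))
    signal = S0 * np.exp(-b * quad)
    if sigma == 0:
        return signal
    rng = np.random.default_rng(seed)
    e1 = rng.normal(0.0, sigma, signal.shape)
    e2 = rng.normal(0.0, sigma, signal.shape)
    return np.sqrt((signal + e1) ** 2 + e2 ** 2)


# ---------------------------------------------------------------------------
# Synthetic cohort
# ---------------------------------------------------------------------------

@dataclass
class GroupParams:
    """Demographic / clinical distributions for one group (means, SDs)."""

    age: tuple = (52.0, 14.0)
    p_male: float = 0.45
    duration: tuple = (0.0, 0.0)   # illness duration, years; fixed 0 for HC
    episodes: tuple = (0.0, 0.0)   # depressive episode count; fixed 0 for HC


# Table-style defaults for a euthymic mood-disorder cohort: three groups of
# 30, HC clinical variables zero-filled.
_DEFAULT_GROUP_PARAMS = {
    "MDD": GroupParams(age=(54.0, 12.4), p_male=11 / 30, duration=(8.6, 9.8), episodes=(3.2, 4.2)),
    "BD": GroupParams(age=(50.8, 14.9), p_male=15 / 30, duration=(19.7, 14.3), episodes=(8.9, 7.8)),
    "HC": GroupParams(age=(52.2, 15.3), p_male=13 / 30, duration=(0.0, 0.0), episodes=(0.0, 0.0)),
}

# cognition score (mean, sd) per group
_DEFAULT_SCORES = {
    "RVP_A'": {"MDD": (0.92, 0.06), "BD": (0.88, 0.05), "HC": (0.93, 0.05)},
    "RTI_5choice_ms": {"MDD": (316.5, 48.7), "BD": (318.7, 51.6), "HC": (284.8, 35.5)},
    "IED_total_errors": {"MDD": (15.3, 14.1), "BD": (35.3, 37.9), "HC": (12.8, 11.0)},
}


def _default_effects():
    return {("BD", "body_cc_L"): -0.05, ("BD", "body_cc_R"): -0.05}


@dataclass
class CohortSpec:
    """Statistical structure of the synthetic three-group cohort.

    Per-tract FA is Normal(baseline + group offset, fa_sd) per subject.
    ``effects`` maps (group, tract) to an additive FA offset; default is a
    -0.05 reduction in the bilateral body of the corpus callosum in the BD
    group.  ``corr_target = (group, tract, score, r)`` injects an exact
    population correlation between that tract's FA and that score within
    that group (see :func:`make_cohort`).
    """

    n_per_group: int = 30
    tracts: tuple = JHU_TRACTS_54
    fa_baseline: float = 0.45
    fa_sd: float = 0.03
    effects: dict = _field(default_factory=_default_effects)
    group_params: dict = _field(default_factory=lambda: dict(_DEFAULT_GROUP_PARAMS))
    scores: dict = _field(default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_SCORES.items()})
    corr_target: tuple | None = ("BD", "body_cc_L", "RVP_A'", 0.387)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 3:
            raise ValueError("group sizes must be >= 3")
        if self.fa_sd <= 0:
            raise ValueError("fa_sd must be > 0")
        if self.corr_target is not None:
            r = self.corr_target[3]
            if not (-1.0 < r < 1.0):
                raise ValueError(f"target correlation must lie in (-1, 1), got {r}")
            if self.corr_target[0] not in GROUPS:
                raise ValueError(f"unknown group {self.corr_target[0]!r} in corr_target")
            if self.corr_target[1] not in self.tracts:
                raise ValueError(f"unknown tract {self.corr_target[1]!r} in corr_target")


def make_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate the subjects x (covariates, scores, tract FA) cohort table.

    Correlation injection: within the designated group the target score is
    generated as ``mu_s + r * (sd_s / sd_FA) * (FA - mu_FA) + eps`` with
    ``eps ~ Normal(0, sd_s^2 (1 - r^2))``, so the population correlation
    equals ``r`` exactly while the score keeps its specified mean and SD.

    Illness duration and episode counts are clipped at 0 (they are counts /
    nonnegative durations); for HC they are fixed to 0 by construction.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    fa_blocks = []
    sid = 0
    for group in GROUPS:
        gp = spec.group_params[group]
        n = spec.n_per_group
        age = rng.normal(gp.age[0], gp.age[1], n)
        gender = (rng.random(n) < gp.p_male).astype(int)  # 1 = male
        if group == "HC":
            duration = np.zeros(n)
            episodes = np.zeros(n)
        else:
            duration = np.clip(rng.normal(gp.duration[0], gp.duration[1], n), 0.0, None)
            episodes = np.clip(rng.normal(gp.episodes[0], gp.episodes[1], n), 0.0, None)

        fa = np.empty((n, len(spec.tracts)))
        for j, tract in enumerate(spec.tracts):
            mean = spec.fa_baseline + spec.effects.get((group, tract), 0.0)
            fa[:, j] = rng.normal(mean, spec.fa_sd, n)

        score_cols = {}
        for name, per_group in spec.scores.items():
            mu_s, sd_s = per_group[group]
            if (spec.corr_target is not None
                    and spec.corr_target[0] == group and spec.corr_target[2] == name):
                _, tract, _, r = spec.corr_target
                j = spec.tracts.index(tract)
                mu_fa = spec.fa_baseline + spec.effects.get((group, tract), 0.0)
                slope = r * sd_s / spec.fa_sd
                eps = rng.normal(0.0, sd_s * math.sqrt(1.0 - r * r), n)
                score_cols[name] = mu_s + slope * (fa[:, j] - mu_fa) + eps
            else:
                score_cols[name] = rng.normal(mu_s, sd_s, n)

        for i in range(n):
            rows.append({
                "subject_id": f"sub-{sid:04d}",
                "group": group,
                "age": age[i],
                "gender": int(gender[i]),
                "duration_illness": duration[i],
                "n_episodes": episodes[i],
                **{name: vals[i] for name, vals in score_cols.items()},
            })
            sid += 1
        fa_blocks.append(fa)

    table = pd.DataFrame(rows)
    fa_all = np.vstack(fa_blocks)
    for j, tract in enumerate(spec.tracts):
        table[tract] = fa_all[:, j]
    return table
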
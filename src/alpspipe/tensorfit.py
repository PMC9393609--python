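"""Diffusion tensor reconstruction by log-linear least squares.

The monoexponential signal model ``S_i = s0 * exp(-b_i g_i^T D g_i)``
becomes linear after taking logs:

    ln S_i = ln s0 - b_i g_i^T D g_i,

a system of N equations in 7 unknowns (6 independent tensor components
plus ln s0) solved per voxel by ordinary least squares.  On noiseless
input this inversion is exact.  An iteratively reweighted variant (WLS,
weights = squared predicted signals) is available behind a flag for noisy
data; it is off by default so that the estimator stays closed-form.

No positive-definiteness projection is applied to fitted tensors; negative
diagonal entries are clamped (and counted) only when axis-diffusivity maps
are extracted, which keeps the estimator linear.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .schemes import GradientScheme, SchemeError
from .synthcohort import DWIVolume

__all__ = [
    "DiffusionTensorField",
    "AxisDiffusivityMaps",
    "fit_tensor_lls",
    "axis_diffusivities",
    "fractional_anisotropy",
    "design_matrix",
]

# fraction of the voxel's s0 estimate used as the log floor for
# nonpositive signals
_SIGNAL_FLOOR_FRACTION = 1e-6


@dataclass
class DiffusionTensorField:
    """Per-voxel symmetric diffusion tensors on the image grid.

    ``components`` has shape (X, Y, Z, 6) ordered
    (Dxx, Dxy, Dxz, Dyy, Dyz, Dzz) in mm^2/s; ``log_s0`` is the fitted
    log-intercept; ``mask`` flags voxels whose fit is usable — invalid
    voxels (background / fit failure) are excluded from all downstream
    means.
    """

    components: np.ndarray
    log_s0: np.ndarray
    mask: np.ndarray
    voxel_size_mm: float = 2.0

    def __post_init__(self) -> None:
        if self.components.ndim != 4 or self.components.shape[3] != 6:
            raise ValueError("components must have shape (X, Y, Z, 6)")
        if self.mask.shape != self.components.shape[:3]:
            raise ValueError("mask shape mismatch")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.components.shape[:3]

    def as_matrices(self) -> np.ndarray:
        """(X, Y, Z, 3, 3) symmetric matrix view of the tensor field."""
        c = self.components
        m = np.empty(self.shape + (3, 3))
        m[..., 0, 0] = c[..., 0]
        m[..., 0, 1] = m[..., 1, 0] = c[..., 1]
        m[..., 0, 2] = m[..., 2, 0] = c[..., 2]
        m[..., 1, 1] = c[..., 3]
        m[..., 1, 2] = m[..., 2, 1] = c[..., 4]
        m[..., 2, 2] = c[..., 5]
        return m


@dataclass
class AxisDiffusivityMaps:
    """Image-frame axis diffusivities Dxx, Dyy, Dzz (tensor diagonal).

    The ALPS readout is defined on the tensor diagonal in the image frame,
    not on eigenvalues, so no eigendecomposition is involved.  Negative
    fitted diagonals are clamped to zero; ``n_clamped`` counts clamped
    entries over the valid voxels.
    """

    dxx: np.ndarray
    dyy: np.ndarray
    dzz: np.ndarray
    mask: np.ndarray
    n_clamped: int = 0

    def axis(self, name: str) -> np.ndarray:
        return {"Dxx": self.dxx, "Dyy": self.dyy, "Dzz": self.dzz}[name]


def design_matrix(scheme: GradientScheme) -> np.ndarray:
    """(N, 7) log-linear design: columns [1, -B] for [ln s0, d]."""
    return np.hstack([np.ones((len(scheme), 1)), -scheme.b_matrix()])


def fit_tensor_lls(
    dwi: DWIVolume,
    scheme: GradientScheme | None = None,
    weighted: bool = False,
    n_wls_iter: int = 2,
) -> DiffusionTensorField:
    """Fit a diffusion tensor per voxel from a DWI volume.

    Ordinary least squares on the log signal by default; set
    ``weighted=True`` for iteratively reweighted (WLS) refinement.
    Voxels whose signal is entirely nonpositive, or where more than half
    the signals needed flooring before the log, are marked invalid rather
    than raising.
    """
    scheme = scheme or dwi.scheme
    if dwi.data.shape[3] != len(scheme):
        raise SchemeError("DWI volume count does not match scheme length")
    A = design_matrix(scheme)
    if np.linalg.matrix_rank(A) < 7:
        raise SchemeError(
            "degenerate direction set: design matrix is rank deficient "
            "(need >= 6 non-collinear b>0 directions)"
        )

    shape = dwi.shape
    S = dwi.data.reshape(-1, len(scheme))
    b0 = scheme.bvals == 0
    s0_est = S[:, b0].mean(axis=1)
    valid = s0_est > 0

    floor = np.where(valid, s0_est, 1.0)[:, None] * _SIGNAL_FLOOR_FRACTION
    needs_floor = S < floor
    valid &= needs_floor.sum(axis=1) <= len(scheme) / 2
    logS = np.log(np.maximum(S, floor))

    # OLS: one pseudoinverse for the whole volume
    coef = (np.linalg.pinv(A) @ logS.T).T  # (V, 7)
    if weighted:
        for _ in range(n_wls_iter):
            w = np.exp(A @ coef.T).T  # predicted signals as weights
            w = np.clip(w, 1e-12, None)
            for v in np.nonzero(valid)[0]:
                Aw = A * w[v, :, None]
                coef[v] = np.linalg.lstsq(Aw, w[v] * logS[v], rcond=None)[0]

    comps = coef[:, 1:].reshape(shape + (6,))
    log_s0 = coef[:, 0].reshape(shape)
    return DiffusionTensorField(
        components=comps,
        log_s0=log_s0,
        mask=valid.reshape(shape),
        voxel_size_mm=dwi.voxel_size_mm,
    )


def axis_diffusivities(field: DiffusionTensorField) -> AxisDiffusivityMaps:
    """Extract the tensor diagonal as three axis-diffusivity maps.

    Negative diagonal values (possible under noise, since the fit is not
    constrained) are clamped to 0; the clamp count covers valid voxels
    only.
    """
    c = field.components
    maps = [c[..., 0].copy(), c[..., 3].copy(), c[..., 5].copy()]
    n_clamped = 0
    for m in maps:
        neg = (m < 0) & field.mask
        n_clamped += int(neg.sum())
        m[m < 0] = 0.0
    return AxisDiffusivityMaps(
        dxx=maps[0], dyy=maps[1], dzz=maps[2],
        mask=field.mask.copy(), n_clamped=n_clamped,
    )


def fractional_anisotropy(field: DiffusionTensorField) -> np.ndarray:
    """Per-voxel fractional anisotropy in [0, 1].

    FA = sqrt(3/2) * ||lambda - mean(lambda)|| / ||lambda||, from the
    tensor eigenvalues; zero tensors map to FA = 0.  Provided as a QC aid
    for checking phantom fiber orientation and anisotropy.
    """
    lam = np.linalg.eigvalsh(field.as_matrices())
    mean = lam.mean(axis=-1, keepdims=True)
    num = ((lam - mean) ** 2).sum(axis=-1)
    den = (lam ** 2).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * num / den)
    fa[den == 0] = 0.0
    return np.clip(fa, 0.0, 1.0)
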
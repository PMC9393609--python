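"""Diffusion gradient schemes and FSL-style bval/bvec I/O.

A :class:`GradientScheme` pairs b-values (s/mm^2) with unit gradient
directions.  The default scheme mimics a routine single-shell DTI protocol:
one unweighted (b=0) volume followed by 32 directions at b = 1000 s/mm^2.
The direction table was obtained once by minimising the antipodally
symmetric electrostatic (Coulomb) energy of 32 axes on the unit sphere and
is frozen here so every run uses the identical scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "GradientScheme",
    "SchemeError",
    "default_scheme",
    "read_fsl_gradients",
    "write_fsl_gradients",
]

DEFAULT_BVALUE = 1000.0  # s/mm^2

# 32 unit axes from deterministic electrostatic-repulsion optimisation,
# flipped into the z >= 0 hemisphere.  Minimum inter-axis angle ~24.8 deg.
DIRECTIONS_32 = np.array([
    (-0.163930663322247, -0.290613292560435, +0.942693296788468),
    (+0.629689050102558, -0.036274052769644, +0.775999931234921),
    (-0.380108152487897, -0.827215989392492, +0.413801279971001),
    (-0.648097853231714, +0.382727340890282, +0.658398781265197),
    (-0.031300789604127, +0.981740716217077, +0.187631092017659),
    (-0.789185692786081, +0.562258407031730, +0.247085867713828),
    (+0.601993405584705, +0.400722126223920, +0.690670483796079),
    (+0.403969088440803, +0.913462087060502, +0.048948861962034),
    (+0.195293466266687, +0.474692623357921, +0.858211731079876),
    (-0.966171176140646, -0.251519885680532, +0.057017589411109),
    (+0.895141693567929, +0.210990616568234, +0.392688563821886),
    (+0.604078749709461, -0.487721106592245, +0.630251526244792),
    (+0.262837960557011, -0.403108603641342, +0.876595494033912),
    (-0.442607210833793, +0.789552745963906, +0.425094481567081),
    (-0.587434041404983, -0.049956588922631, +0.807728658784511),
    (-0.978318900651927, +0.207076969780206, +0.003355177171458),
    (+0.007014698771901, +0.812419676363441, +0.583030928389448),
    (-0.806027239326256, -0.325780127804664, +0.494153212871951),
    (+0.447519899982517, -0.894172307421742, +0.013484204081645),
    (-0.729904460170385, -0.652552870829227, +0.203504864305286),
    (+0.361902411859230, -0.806317490262580, +0.467844791770867),
    (+0.758845447604814, +0.606731847604884, +0.236706678721604),
    (-0.471510101309205, -0.515158662479791, +0.715744211876991),
    (+0.236760215401627, +0.045231020735388, +0.970514685703524),
    (-0.209232751942411, +0.152669377153770, +0.965874586472843),
    (-0.898979632781150, +0.100946269042759, +0.426198862751904),
    (+0.008124347339403, -0.966935351625966, +0.254892174764699),
    (+0.756761160787738, -0.622825736803161, +0.198495962424418),
    (+0.422177911025805, +0.767878515607227, +0.481797049296412),
    (-0.270921431380916, +0.541886438164374, +0.795588251642798),
    (-0.024927360190179, -0.712264177673390, +0.701468721980673),
    (+0.882275168754219, -0.217671809819788, +0.417384127404832),
])


class SchemeError(ValueError):
    """Raised for gradient schemes that cannot support a tensor fit."""


@dataclass(frozen=True)
class GradientScheme:
    """b-values and unit gradient directions of a diffusion acquisition.

    Parameters
    ----------
    bvals
        Length-N array of b-values in s/mm^2.
    bvecs
        (N, 3) array of gradient directions.  Every b > 0 direction must
        be a unit vector; the zero vector is permitted only where b = 0.
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float).ravel()
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.ndim != 2 or bvecs.shape[1] != 3:
            raise SchemeError(f"bvecs must be (N, 3), got {bvecs.shape}")
        if bvals.shape[0] != bvecs.shape[0]:
            raise SchemeError(
                f"{bvals.shape[0]} b-values but {bvecs.shape[0]} directions"
            )
        if np.any(bvals < 0):
            raise SchemeError("negative b-value")
        weighted = bvals > 0
        if np.count_nonzero(~weighted) < 1:
            raise SchemeError("scheme needs at least one b=0 entry")
        if np.count_nonzero(weighted) < 6:
            raise SchemeError("scheme needs at least six b>0 directions")
        norms = np.linalg.norm(bvecs[weighted], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise SchemeError("b>0 directions must be unit vectors (|norm-1| <= 1e-6)")
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    def __len__(self) -> int:
        return self.bvals.shape[0]

    @property
    def n_weighted(self) -> int:
        return int(np.count_nonzero(self.bvals > 0))

    def b_matrix(self) -> np.ndarray:
        """(N, 6) matrix B such that b * g^T D g = B @ d.

        ``d`` holds the tensor components in the order
        (Dxx, Dxy, Dxz, Dyy, Dyz, Dzz); the mixed terms carry the factor 2
        of the symmetric quadratic form.
        """
        gx, gy, gz = self.bvecs.T
        cols = np.stack(
            [gx * gx, 2 * gx * gy, 2 * gx * gz, gy * gy, 2 * gy * gz, gz * gz],
            axis=1,
        )
        return self.bvals[:, None] * cols


def default_scheme(bvalue: float = DEFAULT_BVALUE) -> GradientScheme:
    """One b=0 volume plus the frozen 32-direction shell at ``bvalue``."""
    bvals = np.concatenate([[0.0], np.full(len(DIRECTIONS_32), float(bvalue))])
    bvecs = np.vstack([np.zeros(3), DIRECTIONS_32])
    return GradientScheme(bvals, bvecs)


def read_fsl_gradients(bval_path: str | Path, bvec_path: str | Path) -> GradientScheme:
    """Read FSL-dialect ``bvals`` (1 x N) and ``bvecs`` (3 x N) text files."""
    bvals = np.loadtxt(bval_path, ndmin=1).ravel()
    bvecs = np.loadtxt(bvec_path, ndmin=2)
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape == (3, 3):
        # ambiguous square case: FSL convention is one row per axis
        bvecs = bvecs.T
    return GradientScheme(bvals, bvecs)


def write_fsl_gradients(
    scheme: GradientScheme, bval_path: str | Path, bvec_path: str | Path
) -> None:
    """Write the scheme as FSL ``bvals``/``bvecs`` (3 rows x N columns)."""
    np.savetxt(bval_path, scheme.bvals[None, :], fmt="%.6g")
    np.savetxt(bvec_path, scheme.bvecs.T, fmt="%.15g")
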
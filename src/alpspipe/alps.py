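"""The ALPS index: diffusivity analysis along the perivascular space.

At the level of the lateral-ventricle body, projection fibers run along z,
association fibers along y, and the perivascular spaces of the medullary
veins along x — perpendicular to both fiber families.  Water movement
along the perivascular space therefore raises the x-axis diffusivity in
the projection and association ROIs above what the fibers themselves
produce, and the ratio

    ALPS = mean(Dxx_projection, Dxx_association)
           / mean(Dyy_projection, Dzz_association)

isolates that perivascular contribution: 1 under isotropy, larger when
perivascular diffusion is preserved.  ROI diffusivities are averaged after
discarding one maximum and one minimum voxel value per (fiber, axis) cell.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .tensorfit import AxisDiffusivityMaps

__all__ = [
    "FiberROISet",
    "FiberAxisDiffusivities",
    "AlpsIndex",
    "RoiError",
    "trimmed_mean_excluding_extremes",
    "extract_fiber_axis_diffusivities",
    "alps_index",
    "alps_from_maps",
]

FIBERS = ("projection", "association", "subcortical")
AXES = ("Dxx", "Dyy", "Dzz")
ROI_LABELS = {"projection": 1, "association": 2, "subcortical": 3}


class RoiError(ValueError):
    """Raised when an ROI cannot support the trimmed-mean readout."""


@dataclass(frozen=True)
class FiberROISet:
    """Disjoint voxel masks for the three fiber ROIs."""

    projection: np.ndarray
    association: np.ndarray
    subcortical: np.ndarray

    def __post_init__(self) -> None:
        shapes = {m.shape for m in self.masks().values()}
        if len(shapes) != 1:
            raise RoiError("ROI masks must share one grid shape")
        ms = self.masks()
        for i, a in enumerate(FIBERS):
            for b in FIBERS[i + 1:]:
                if np.any(ms[a] & ms[b]):
                    raise RoiError(f"ROIs {a} and {b} overlap")

    def masks(self) -> dict[str, np.ndarray]:
        return {
            "projection": np.asarray(self.projection, dtype=bool),
            "association": np.asarray(self.association, dtype=bool),
            "subcortical": np.asarray(self.subcortical, dtype=bool),
        }

    @classmethod
    def from_labels(cls, labels: np.ndarray) -> "FiberROISet":
        """Build from an integer label volume (1=proj, 2=assoc, 3=subcort)."""
        labels = np.asarray(labels)
        return cls(**{f: labels == code for f, code in ROI_LABELS.items()})

    def to_labels(self) -> np.ndarray:
        out = np.zeros(self.projection.shape, dtype=np.int16)
        for fiber, code in ROI_LABELS.items():
            out[self.masks()[fiber]] = code
        return out


@dataclass(frozen=True)
class FiberAxisDiffusivities:
    """The nine trimmed ROI-mean diffusivities (mm^2/s) and voxel counts.

    ``values[fiber][axis]`` is the trimmed mean of that axis map over the
    fiber ROI's valid voxels; ``counts`` gives the number of contributing
    voxels (mask size minus the two excluded extremes).
    """

    values: Mapping[str, Mapping[str, float]]
    counts: Mapping[str, Mapping[str, int]]

    @property
    def dxx_projection(self) -> float:
        return self.values["projection"]["Dxx"]

    @property
    def dxx_association(self) -> float:
        return self.values["association"]["Dxx"]

    @property
    def dyy_projection(self) -> float:
        return self.values["projection"]["Dyy"]

    @property
    def dzz_association(self) -> float:
        return self.values["association"]["Dzz"]

    def flat(self) -> dict[str, float]:
        """All nine cells keyed 'Dxx_projection' ... 'Dzz_subcortical'."""
        return {
            f"{axis}_{fiber}": self.values[fiber][axis]
            for fiber in FIBERS for axis in AXES
        }


@dataclass(frozen=True)
class AlpsIndex:
    """Dimensionless perivascular diffusivity ratio; 1 under isotropy."""

    value: float

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ValueError(f"ALPS index must be positive, got {self.value}")

    def __float__(self) -> float:
        return self.value


def trimmed_mean_excluding_extremes(values: Sequence[float] | np.ndarray) -> float:
    """Mean after removing one occurrence of the max and one of the min.

    With ties, only a single maximal and a single minimal value are
    dropped, so exactly ``len(values) - 2`` entries contribute.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 3:
        raise ValueError(
            f"need at least 3 values to trim the extremes, got {v.size}"
        )
    return float((v.sum() - v.max() - v.min()) / (v.size - 2))


def extract_fiber_axis_diffusivities(
    maps: AxisDiffusivityMaps, rois: FiberROISet
) -> FiberAxisDiffusivities:
    """Trimmed ROI means of Dxx/Dyy/Dzz for each fiber.

    Trimming is applied independently per (fiber, axis) cell: the voxel
    holding the maximal Dxx of an ROI still contributes to that ROI's Dyy
    and Dzz means.  Only voxels inside the validity mask enter.
    """
    values: dict[str, dict[str, float]] = {}
    counts: dict[str, dict[str, int]] = {}
    for fiber, mask in rois.masks().items():
        if mask.shape != maps.mask.shape:
            raise RoiError("ROI grid does not match the diffusivity maps")
        sel = mask & maps.mask
        n = int(sel.sum())
        if n < 3:
            raise RoiError(
                f"ROI {fiber!r} has {n} valid voxels; >= 3 required for the "
                "trimmed mean"
            )
        values[fiber] = {}
        counts[fiber] = {}
        for axis in AXES:
            values[fiber][axis] = trimmed_mean_excluding_extremes(
                maps.axis(axis)[sel]
            )
            counts[fiber][axis] = n - 2
    return FiberAxisDiffusivities(values=values, counts=counts)


def alps_index(fad: FiberAxisDiffusivities) -> AlpsIndex:
    """ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc).

    Only these four cells enter the index; the other five are carried for
    per-axis group comparisons.
    """
    num_parts = (fad.dxx_projection, fad.dxx_association)
    den_parts = (fad.dyy_projection, fad.dzz_association)
    if any(x <= 0 for x in num_parts + den_parts):
        raise ValueError(
            "ALPS inputs must be positive: "
            f"Dxx_proj={num_parts[0]}, Dxx_assoc={num_parts[1]}, "
            f"Dyy_proj={den_parts[0]}, Dzz_assoc={den_parts[1]}"
        )
    return AlpsIndex(value=(sum(num_parts) / 2) / (sum(den_parts) / 2))


def alps_from_maps(
    maps: AxisDiffusivityMaps, rois: FiberROISet
) -> tuple[FiberAxisDiffusivities, AlpsIndex]:
    """Convenience: extraction and index in one call."""
    fad = extract_fiber_axis_diffusivities(maps, rois)
    return fad, alps_index(fad)


def bilateral_alps_index(
    maps: AxisDiffusivityMaps, left: FiberROISet, right: FiberROISet
) -> AlpsIndex:
    """Average of the per-hemisphere indices over two ROI sets.

    Optional mode for bilateral ROI placements; the default analysis uses
    a single ROI set per subject.
    """
    _, li = alps_from_maps(maps, left)
    _, ri = alps_from_maps(maps, right)
    return AlpsIndex(value=(li.value + ri.value) / 2)
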
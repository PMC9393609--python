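"""Synthetic diffusion phantoms and cohorts for perivascular-flow studies.

The phantom mimics the white-matter anatomy at the level of the lateral
ventricle body, where the ALPS method is defined: projection fibers run
superior-inferior (z), association fibers anterior-posterior (y),
subcortical fibers left-right (x), and the perivascular spaces of the
medullary veins run along x, orthogonal to both projection and association
fibers.  A dimensionless glymphatic coefficient ``g`` in [0, 1] scales the
extra x-axis diffusivity contributed by water movement along the
perivascular space, so downstream analysis can be validated against a known
ground truth.

Coordinate convention is RAS-like: x = left-right, y = anterior-posterior,
z = superior-inferior, recorded in NIfTI affines as a scaled identity.

The cohort generator draws per-subject coefficients from truncated normals
and emulates the covariate structure of an early-stage chronic kidney
disease (CKD) case-control study: 18 patients (CKD stages 3a/3b/4, heavy
diabetes and hypertension comorbidity) against 18 age- and sex-matched
healthy controls.  Default group coefficients are calibrated so the group
mean ALPS indices land at 1.2594 (patients) and 1.4777 (controls).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .schemes import GradientScheme, default_scheme

__all__ = [
    "PhantomGeometry",
    "DiffusivityProfile",
    "DWIVolume",
    "SubjectRecord",
    "CohortSubject",
    "GeometryError",
    "ProfileError",
    "build_phantom",
    "simulate_dwi",
    "generate_cohort",
    "cohort_covariates",
    "default_geometry",
    "default_profile",
]

FIBERS = ("projection", "association", "subcortical")

FREE_WATER_BOUND = 4e-3  # mm^2/s, upper sanity bound on any diffusivity


class GeometryError(ValueError):
    """Invalid phantom geometry (overlapping or undersized fiber boxes)."""


class ProfileError(ValueError):
    """Invalid diffusivity profile (nonpositive or unphysical values)."""


Box = tuple[tuple[int, int], tuple[int, int], tuple[int, int]]


@dataclass(frozen=True)
class PhantomGeometry:
    """Voxel grid with three disjoint axis-aligned fiber boxes.

    ``boxes`` maps each fiber name to ((x0, x1), (y0, y1), (z0, z1)) in
    half-open voxel index ranges.  Everything outside the boxes is
    isotropic background.
    """

    shape: tuple[int, int, int] = (16, 16, 6)
    voxel_size_mm: float = 2.0
    boxes: Mapping[str, Box] = field(
        default_factory=lambda: {
            "projection": ((2, 6), (2, 6), (1, 5)),
            "association": ((10, 14), (2, 6), (1, 5)),
            "subcortical": ((2, 6), (10, 14), (1, 5)),
        }
    )

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise GeometryError(f"bad grid shape {self.shape}")
        if self.voxel_size_mm <= 0:
            raise GeometryError("voxel size must be positive")
        if set(self.boxes) != set(FIBERS):
            raise GeometryError(f"boxes must be keyed by {FIBERS}")
        masks = {name: self.mask(name) for name in FIBERS}
        for name, m in masks.items():
            if m.sum() < 3:
                raise GeometryError(f"{name} box has < 3 voxels")
        for i, a in enumerate(FIBERS):
            for b in FIBERS[i + 1:]:
                if np.any(masks[a] & masks[b]):
                    raise GeometryError(f"fiber boxes {a} and {b} overlap")

    def mask(self, fiber: str) -> np.ndarray:
        (x0, x1), (y0, y1), (z0, z1) = self.boxes[fiber]
        for lo, hi, n in zip((x0, y0, z0), (x1, y1, z1), self.shape):
            if not (0 <= lo < hi <= n):
                raise GeometryError(
                    f"{fiber} box range ({lo}, {hi}) outside grid {self.shape}"
                )
        m = np.zeros(self.shape, dtype=bool)
        m[x0:x1, y0:y1, z0:z1] = True
        return m

    @property
    def affine(self) -> np.ndarray:
        a = np.diag([self.voxel_size_mm] * 3 + [1.0])
        return a


@dataclass(frozen=True)
class DiffusivityProfile:
    """Per-region diffusivities (mm^2/s) defining the phantom tensors.

    Each fiber has a principal-axis and a minor-axis diffusivity; the
    projection and association fibers additionally have a perivascular
    baseline along x, to which ``g * delta_pv`` is added.  The defaults
    place the fiber diffusivities at values typical of deep white matter
    and are calibrated so the noiseless ALPS index is

        ALPS(g) = 1.095675 + 0.54575 * g,

    i.e. 1.2594 at g = 0.3 and 1.4777 at g = 0.7.
    """

    projection_principal: float = 1.05e-3   # Dzz along the fiber
    projection_minor: float = 5.0e-4        # Dyy across fiber and PVS
    projection_x_baseline: float = 4.5e-4   # Dxx before perivascular term
    association_principal: float = 1.05e-3  # Dyy along the fiber
    association_minor: float = 4.0e-4       # Dzz across fiber and PVS
    association_x_baseline: float = 5.361075e-4
    subcortical_principal: float = 1.1e-3   # Dxx along the fiber
    subcortical_minor: float = 6.5e-4       # Dyy = Dzz
    delta_pv: float = 2.455875e-4           # perivascular gain at g = 1
    background: float = 8.0e-4              # isotropic surround

    def __post_init__(self) -> None:
        for name in (
            "projection_principal", "projection_minor", "projection_x_baseline",
            "association_principal", "association_minor", "association_x_baseline",
            "subcortical_principal", "subcortical_minor", "background",
        ):
            v = getattr(self, name)
            if not (0 < v < FREE_WATER_BOUND):
                raise ProfileError(
                    f"{name} = {v} outside (0, {FREE_WATER_BOUND}) mm^2/s"
                )
        if self.delta_pv < 0 or self.delta_pv >= FREE_WATER_BOUND:
            raise ProfileError(f"delta_pv = {self.delta_pv} out of range")

    def expected_alps(self, g: float) -> float:
        """Closed-form noiseless ALPS index of the phantom at coefficient g."""
        num = (self.projection_x_baseline + self.association_x_baseline) / 2 \
            + g * self.delta_pv
        den = (self.projection_minor + self.association_minor) / 2
        return num / den


@dataclass(frozen=True)
class DWIVolume:
    """A 4D diffusion-weighted acquisition tied to its gradient scheme."""

    data: np.ndarray  # (X, Y, Z, N), intensities >= 0
    scheme: GradientScheme
    voxel_size_mm: float = 2.0

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 4:
            raise ValueError(f"DWI data must be 4D, got shape {data.shape}")
        if data.shape[3] != len(self.scheme):
            raise ValueError(
                f"{data.shape[3]} volumes but scheme has {len(self.scheme)} entries"
            )
        if np.any(data < 0):
            raise ValueError("negative intensity in DWI volume")
        object.__setattr__(self, "data", data)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass
class SubjectRecord:
    """Group label, covariates and labs for one (synthetic) subject."""

    subject_id: str
    group: str  # "early_ckd" | "control"
    age: float
    sex: str  # "M" | "F"
    dm: bool
    htn: bool
    ckd_stage: str  # "3a" | "3b" | "4" | "none"
    labs: dict[str, float] = field(default_factory=dict)
    g_true: float | None = None  # hidden ground-truth glymphatic coefficient

    def __post_init__(self) -> None:
        if self.group not in ("early_ckd", "control"):
            raise ValueError(f"unknown group {self.group!r}")
        if self.group == "control" and self.ckd_stage != "none":
            raise ValueError("controls must have ckd_stage 'none'")
        if self.group == "early_ckd" and self.ckd_stage not in ("3a", "3b", "4"):
            raise ValueError(f"patient ckd_stage {self.ckd_stage!r} not in 3a/3b/4")


@dataclass
class CohortSubject:
    record: SubjectRecord
    dwi: DWIVolume
    roi_labels: np.ndarray  # integer labels: 0 bg, 1 proj, 2 assoc, 3 subcort


def default_geometry() -> PhantomGeometry:
    return PhantomGeometry()


def default_profile() -> DiffusivityProfile:
    return DiffusivityProfile()


def _rotation_z(angle_deg: float) -> np.ndarray:
    a = math.radians(angle_deg)
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


# component order matches NIfTI tensor convention (Dxx, Dxy, Dxz, Dyy, Dyz, Dzz)
COMP_NAMES = ("Dxx", "Dxy", "Dxz", "Dyy", "Dyz", "Dzz")
_DIAG_IDX = {"Dxx": 0, "Dyy": 3, "Dzz": 5}


def build_phantom(
    geometry: PhantomGeometry | None = None,
    profile: DiffusivityProfile | None = None,
    g: float = 0.0,
    oblique_angle_deg: float = 0.0,
):
    """Construct the tensor field and fiber ROI labels of the phantom.

    Returns ``(tensor_components, roi_labels)`` where the components array
    has shape (X, Y, Z, 6) in the order (Dxx, Dxy, Dxz, Dyy, Dyz, Dzz) and
    the label volume uses 0 = background, 1 = projection, 2 = association,
    3 = subcortical.  ``g`` scales the perivascular x-axis gain added in
    the projection and association regions; ``oblique_angle_deg`` rotates
    the fiber-region tensors about z to probe the (mis)alignment
    sensitivity of the ALPS readout.
    """
    geometry = geometry or default_geometry()
    profile = profile or default_profile()
    if not (0.0 <= g <= 1.0):
        raise ValueError(f"glymphatic coefficient g = {g} outside [0, 1]")

    comps = np.zeros(geometry.shape + (6,))
    comps[..., _DIAG_IDX["Dxx"]] = profile.background
    comps[..., _DIAG_IDX["Dyy"]] = profile.background
    comps[..., _DIAG_IDX["Dzz"]] = profile.background

    pv = g * profile.delta_pv
    diagonals = {
        "projection": (
            profile.projection_x_baseline + pv,
            profile.projection_minor,
            profile.projection_principal,
        ),
        "association": (
            profile.association_x_baseline + pv,
            profile.association_principal,
            profile.association_minor,
        ),
        "subcortical": (
            profile.subcortical_principal,
            profile.subcortical_minor,
            profile.subcortical_minor,
        ),
    }

    labels = np.zeros(geometry.shape, dtype=np.int16)
    rot = _rotation_z(oblique_angle_deg) if oblique_angle_deg else None
    for code, fiber in enumerate(FIBERS, start=1):
        mask = geometry.mask(fiber)
        dxx, dyy, dzz = diagonals[fiber]
        if rot is None:
            comps[mask, 0] = dxx
            comps[mask, 3] = dyy
            comps[mask, 5] = dzz
            comps[mask, 1] = comps[mask, 2] = comps[mask, 4] = 0.0
        else:
            d = rot @ np.diag([dxx, dyy, dzz]) @ rot.T
            comps[mask] = [d[0, 0], d[0, 1], d[0, 2], d[1, 1], d[1, 2], d[2, 2]]
        labels[mask] = code
    return comps, labels


def simulate_dwi(
    tensor_components: np.ndarray,
    scheme: GradientScheme | None = None,
    s0: float = 1000.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
    noise_model: str = "rician",
    voxel_size_mm: float = 2.0,
) -> DWIVolume:
    """Simulate diffusion-weighted signals with the monoexponential model.

    The noiseless signal along direction g_i at b-value b_i is
    ``S_i = s0 * exp(-b_i * g_i^T D g_i)``.  With ``noise_sigma > 0`` the
    default noise model is Rician (magnitude of the signal plus two
    independent Gaussian channels of sd ``noise_sigma``), the distribution
    of magnitude MRI; ``noise_model="gaussian"`` adds a single Gaussian
    channel and clips at zero.
    """
    scheme = scheme or default_scheme()
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if noise_model not in ("rician", "gaussian"):
        raise ValueError(f"unknown noise model {noise_model!r}")
    comps = np.asarray(tensor_components, dtype=float)
    if comps.ndim != 4 or comps.shape[3] != 6:
        raise ValueError("tensor components must have shape (X, Y, Z, 6)")

    bmat = scheme.b_matrix()  # (N, 6)
    attenuation = comps.reshape(-1, 6) @ bmat.T  # (V, N), b * g^T D g
    signal = s0 * np.exp(-attenuation)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        if noise_model == "rician":
            re = signal + rng.normal(0.0, noise_sigma, signal.shape)
            im = rng.normal(0.0, noise_sigma, signal.shape)
            signal = np.hypot(re, im)
        else:
            signal = np.clip(
                signal + rng.normal(0.0, noise_sigma, signal.shape), 0.0, None
            )
    data = signal.reshape(comps.shape[:3] + (len(scheme),))
    return DWIVolume(data=data, scheme=scheme, voxel_size_mm=voxel_size_mm)


# ---------------------------------------------------------------------------
# Cohort covariate model
# ---------------------------------------------------------------------------

# Patient-group laboratory panel: name -> (mean, sd).  eGFR is handled
# separately so it stays consistent with the sampled CKD stage.
PATIENT_LABS: dict[str, tuple[float, float]] = {
    "hemoglobin": (11.9, 1.9),        # g/dL
    "hematocrit": (35.7, 5.5),        # %
    "protein": (7.2, 0.6),            # g/dL
    "albumin": (4.0, 0.4),            # g/dL
    "ast": (22.4, 6.6),               # U/L
    "alt": (18.8, 8.2),               # U/L
    "bun": (26.0, 6.4),               # mg/dL
    "creatinine": (1.7, 0.4),         # mg/dL
    "sodium": (140.9, 2.6),           # mmol/L
    "potassium": (4.7, 0.5),          # mmol/L
    "chloride": (106.1, 4.0),         # mmol/L
    "calcium": (8.4, 1.2),            # mg/dL
    "phosphate": (3.6, 0.5),          # mg/dL
    "total_co2": (23.9, 3.0),         # mmol/L
    "total_cholesterol": (153.1, 35.1),  # mg/dL
}

AGE_BY_GROUP = {"early_ckd": (65.9, 9.9), "control": (66.4, 6.3)}
MALE_FRACTION = {"early_ckd": 9 / 18, "control": 11 / 18}
# joint comorbidity composition of the patient group (fractions of n):
# both DM and HTN, DM only, HTN only, neither
COMORBIDITY_FRACTIONS = {"both": 5 / 18, "dm_only": 3 / 18, "htn_only": 8 / 18,
                         "neither": 2 / 18}
STAGE_FRACTIONS = {"3a": 5 / 18, "3b": 10 / 18, "4": 3 / 18}
# eGFR bands (ml/min/1.73 m^2) by stage
EGFR_BANDS = {"3a": (45.0, 59.0), "3b": (30.0, 44.0), "4": (15.0, 29.0)}


def _apportion(fractions: Mapping[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment of n units to the given fractions."""
    quotas = {k: f * n for k, f in fractions.items()}
    counts = {k: int(math.floor(q)) for k, q in quotas.items()}
    short = n - sum(counts.values())
    by_rem = sorted(quotas, key=lambda k: quotas[k] - counts[k], reverse=True)
    for k in by_rem[:short]:
        counts[k] += 1
    return counts


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float,
    lo: float, hi: float, max_attempts: int = 1000,
) -> float:
    if sd == 0:
        if lo <= mean <= hi:
            return mean
        raise ValueError(f"degenerate truncated normal: {mean} outside [{lo}, {hi}]")
    for _ in range(max_attempts):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    raise ValueError(
        f"truncated normal ({mean}, {sd}) on [{lo}, {hi}]: "
        f"no draw accepted in {max_attempts} attempts"
    )


def _patient_records(
    n: int, g_params: tuple[float, float], rng: np.random.Generator,
    start_index: int = 0,
) -> list[SubjectRecord]:
    comorb = _apportion(COMORBIDITY_FRACTIONS, n)
    flags = (
        [(True, True)] * comorb["both"]
        + [(True, False)] * comorb["dm_only"]
        + [(False, True)] * comorb["htn_only"]
        + [(False, False)] * comorb["neither"]
    )
    stages = []
    for stage, k in _apportion(STAGE_FRACTIONS, n).items():
        stages += [stage] * k
    rng.shuffle(flags)
    rng.shuffle(stages)
    records = []
    for i in range(n):
        dm, htn = flags[i]
        stage = stages[i]
        labs = {
            name: float(rng.normal(mu, sd)) for name, (mu, sd) in PATIENT_LABS.items()
        }
        labs["egfr"] = float(rng.uniform(*EGFR_BANDS[stage]))
        records.append(SubjectRecord(
            subject_id=f"ckd{start_index + i + 1:03d}",
            group="early_ckd",
            age=float(rng.normal(*AGE_BY_GROUP["early_ckd"])),
            sex="M" if rng.random() < MALE_FRACTION["early_ckd"] else "F",
            dm=dm, htn=htn, ckd_stage=stage, labs=labs,
            g_true=_truncated_normal(rng, g_params[0], g_params[1], 0.0, 1.0),
        ))
    return records


def _control_records(
    n: int, g_params: tuple[float, float], rng: np.random.Generator,
) -> list[SubjectRecord]:
    records = []
    for i in range(n):
        records.append(SubjectRecord(
            subject_id=f"ctl{i + 1:03d}",
            group="control",
            age=float(rng.normal(*AGE_BY_GROUP["control"])),
            sex="M" if rng.random() < MALE_FRACTION["control"] else "F",
            dm=False, htn=False, ckd_stage="none", labs={},
            g_true=_truncated_normal(rng, g_params[0], g_params[1], 0.0, 1.0),
        ))
    return records


def generate_cohort(
    n_ckd: int = 18,
    n_ctrl: int = 18,
    g_ckd: tuple[float, float] = (0.3, 0.1),
    g_ctrl: tuple[float, float] = (0.7, 0.1),
    profile: DiffusivityProfile | None = None,
    geometry: PhantomGeometry | None = None,
    scheme: GradientScheme | None = None,
    noise_sigma: float = 20.0,
    s0: float = 1000.0,
    seed: int = 0,
    noise_model: str = "rician",
) -> list[CohortSubject]:
    """Generate a full synthetic case-control cohort.

    Each subject gets a glymphatic coefficient drawn from the group's
    truncated normal, the phantom tensor field at that coefficient, and a
    simulated DWI acquisition.  The comorbidity and CKD-stage composition
    of the patient group follows fixed fractions (largest-remainder
    apportionment), so subgroup analyses are well defined at any n.
    Fully reproducible from ``seed``.
    """
    if n_ckd < 2 or n_ctrl < 2:
        raise ValueError("each group needs at least 2 subjects")
    geometry = geometry or default_geometry()
    profile = profile or default_profile()
    scheme = scheme or default_scheme()
    rng = np.random.default_rng(seed)
    records = _patient_records(n_ckd, g_ckd, rng) + _control_records(
        n_ctrl, g_ctrl, rng
    )
    subjects = []
    for rec in records:
        comps, labels = build_phantom(geometry, profile, rec.g_true)
        dwi = simulate_dwi(
            comps, scheme, s0=s0, noise_sigma=noise_sigma,
            seed=int(rng.integers(2**31)), noise_model=noise_model,
            voxel_size_mm=geometry.voxel_size_mm,
        )
        subjects.append(CohortSubject(record=rec, dwi=dwi, roi_labels=labels))
    return subjects


def cohort_covariates(subjects: Sequence[CohortSubject]):
    """Covariate table (one row per subject) as a pandas DataFrame."""
    import pandas as pd

    rows = []
    for s in subjects:
        r = s.record
        row = {
            "subject_id": r.subject_id, "group": r.group, "age": r.age,
            "sex": r.sex, "dm": r.dm, "htn": r.htn, "ckd_stage": r.ckd_stage,
            "g_true": r.g_true,
        }
        row.update(r.labs)
        rows.append(row)
    return pd.DataFrame(rows)
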
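"""Synthetic ground-truth fixtures: crowns, mandibles, whole cases, cohorts.

No deposited patient data exists for this kind of study, so every pipeline
stage is validated against procedurally generated geometry with known
ground truth.  Crowns are rounded boxes with off-centre cusp bumps (1
ridge for incisors, 1 cusp for canines, 2 for premolars, 4 for molars) of
*unequal* heights plus a lateral skew — deliberate asymmetry, because ICP
on a rotationally symmetric shape is ill-posed; the asymmetry is verified
by an explicit self-fit check in the test suite rather than assumed.

A case consists of a T1 mandible slab carrying the three landmarks
(pogonion, left/right mental foramina), a T2 mandible that is the same
slab under a random rigid case transform, 14 predicted crowns on an
elliptical arch (FDI 31-37, 41-47), and achieved crowns displaced from
the predicted ones by per-tooth transforms drawn from N(mu_type,
sigma_type) — injected so that the resulting *prediction differences*
equal the drawn values under the measurement sign convention.  Optional
surface noise displaces vertices along their normals (isotropic Gaussian,
a stand-in for scanner/segmentation roughness).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .crownprep import build_tooth_frame, crop_occlusal_third, tooth_type_of
from .geometry import RigidTransform, SixMeasures, transform_from_six
from .meshio import LandmarkSet, write_landmarks, write_stl

__all__ = [
    "CohortSpec",
    "ARCH_FDI",
    "make_crown",
    "make_mandible",
    "arch_placement",
    "make_case",
    "simulate_cohort_table",
]

#: The study arch: 14 mandibular teeth, left 37..31 then right 41..47.
ARCH_FDI = (37, 36, 35, 34, 33, 32, 31, 41, 42, 43, 44, 45, 46, 47)

# crown extents (buccolingual, mesiodistal, occlusogingival) in mm,
# loosely after average mandibular crown dimensions
_CROWN_DIMS = {
    "incisor": (6.0, 5.5, 9.0),
    "canine": (7.0, 6.5, 10.0),
    "premolar": (8.0, 7.0, 8.0),
    "molar": (10.5, 10.0, 7.5),
}

# cusp bump layout per tooth type: (cx, cy) as fractions of the half-extent,
# height in mm, sigma (mm); unequal heights break rotational symmetry
_CUSPS = {
    "incisor": [((0.25, 0.10), 1.8, (1.0, 2.6))],           # single ridge
    "canine": [((0.22, 0.28), 2.0, (1.6, 1.6))],
    "premolar": [((0.45, 0.18), 2.2, (1.7, 1.7)),
                 ((-0.40, -0.25), 0.9, (1.4, 1.4))],
    "molar": [((0.42, 0.40), 2.2, (1.6, 1.6)),
              ((-0.40, 0.42), 1.2, (1.5, 1.5)),
              ((0.40, -0.42), 0.7, (1.5, 1.5)),
              ((-0.42, -0.40), 1.6, (1.6, 1.6))],
}

_DEFAULT_SIGMA = np.array([1.5, 1.5, 1.5, 0.25, 0.25, 0.25])


def _default_mu() -> dict[str, np.ndarray]:
    return {t: np.zeros(6) for t in _CROWN_DIMS}


def _default_sigma() -> dict[str, np.ndarray]:
    return {t: _DEFAULT_SIGMA.copy() for t in _CROWN_DIMS}


@dataclass
class CohortSpec:
    """Study conditions for a simulated cohort.

    mu / sigma give, per tooth type, the mean and spread of the six
    prediction-difference measures in measurement order
    (phi, theta, psi in degrees; x, y, z in mm).  Defaults: zero mean,
    sigma 1.5 deg / 0.25 mm — sub-clinical spreads typical of aligner
    prediction discrepancies.  noise_sd is the surface-noise standard
    deviation in mm (scanner-scale default 0.02).
    """

    n_patients: int = 5
    mu: dict[str, np.ndarray] = field(default_factory=_default_mu)
    sigma: dict[str, np.ndarray] = field(default_factory=_default_sigma)
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for t in _CROWN_DIMS:
            self.mu[t] = np.asarray(self.mu.get(t, np.zeros(6)), dtype=float)
            self.sigma[t] = np.asarray(self.sigma.get(t, _DEFAULT_SIGMA), dtype=float)
            if np.any(self.sigma[t] < 0):
                raise ValueError("sigma must be non-negative")


def _bump_field(xy: np.ndarray, dims, cusps, rng: np.random.Generator) -> np.ndarray:
    """Sum of Gaussian cusp bumps evaluated at the (n, 2) top-face coords."""
    dz = np.zeros(len(xy))
    for (fx, fy), height, (sx, sy) in cusps:
        cx = fx * dims[0] / 2 + rng.normal(0, 0.08)
        cy = fy * dims[1] / 2 + rng.normal(0, 0.08)
        dz += height * np.exp(
            -((xy[:, 0] - cx) ** 2) / (2 * sx**2)
            - ((xy[:, 1] - cy) ** 2) / (2 * sy**2)
        )
    return dz


def make_crown(
    tooth_type: str,
    dims: tuple[float, float, float] | None = None,
    resolution: int = 3,
    seed: int = 0,
) -> tuple[trimesh.Trimesh, tuple[np.ndarray, np.ndarray]]:
    """Watertight crown-like mesh with its true (occlusal, buccal) hints.

    A subdivided box carries tooth-type-specific cusp bumps on its top
    face plus a lateral skew of the occlusal region, so the shape has no
    rotational symmetry and the rigid self-fit is well-posed.  The crown
    is centred so its own axes coincide with (x buccal, y mesial,
    z occlusal).  Deterministic for a fixed seed.
    """
    if tooth_type not in _CROWN_DIMS:
        raise ValueError(f"unknown tooth type {tooth_type!r}")
    if resolution < 2:
        raise ValueError("resolution too low to break symmetry (need >= 2)")
    dims = np.asarray(dims if dims is not None else _CROWN_DIMS[tooth_type], float)
    rng = np.random.default_rng(seed)
    mesh = trimesh.creation.box(extents=dims)
    for _ in range(resolution):
        mesh = mesh.subdivide()
    v = np.asarray(mesh.vertices, dtype=float).copy()
    z_top = dims[2] / 2.0
    # weight 0 at mid-height -> 1 at the top face keeps the solid closed
    w = np.clip(v[:, 2] / z_top, 0.0, 1.0) ** 2
    dz = _bump_field(v[:, :2], dims, _CUSPS[tooth_type], rng)
    v[:, 2] += w * dz
    # lateral skew of the occlusal part: breaks mirror symmetry
    v[:, 1] += w * 0.6 * (v[:, 0] / (dims[0] / 2.0))
    mesh.vertices = v
    return mesh, (np.array([0.0, 0.0, 1.0]), np.array([1.0, 0.0, 0.0]))


def make_mandible(seed: int = 0, resolution: int = 4) -> tuple[trimesh.Trimesh, LandmarkSet]:
    """Mandible stand-in: a slab with a chin prominence, two mental-foramen
    pits and an asymmetric ridge (so rigid self-fits are unique), plus the
    three landmark coordinates rigidly attached to it."""
    rng = np.random.default_rng(seed)
    extents = np.array([60.0, 40.0, 16.0])
    mesh = trimesh.creation.box(extents=extents)
    for _ in range(resolution):
        mesh = mesh.subdivide()
    v = np.asarray(mesh.vertices, dtype=float).copy()
    front = np.clip(-v[:, 1] / 20.0, 0.0, 1.0) ** 2      # weight on the y = -20 face
    # chin prominence around (0, -20, -3)
    chin = 6.0 * np.exp(-(v[:, 0] ** 2 + (v[:, 2] + 3.0) ** 2) / (2 * 6.0**2))
    # mental foramen pits at (+/-22, -20, +2)
    pits = np.zeros(len(v))
    for sx in (-1.0, 1.0):
        pits += 2.0 * np.exp(
            -((v[:, 0] - sx * 22.0) ** 2 + (v[:, 2] - 2.0) ** 2) / (2 * 2.5**2)
        )
    # asymmetric ridge on the top face breaks left-right mirror symmetry
    top = np.clip(v[:, 2] / 8.0, 0.0, 1.0) ** 2
    rx, ry = 12.0 + rng.normal(0, 0.5), 5.0 + rng.normal(0, 0.5)
    ridge = 3.0 * np.exp(
        -((v[:, 0] - rx) ** 2 + (v[:, 1] - ry) ** 2) / (2 * 7.0**2)
    ) + 1.5 * np.exp(
        -((v[:, 0] + 20.0) ** 2 + (v[:, 1] + 8.0) ** 2) / (2 * 5.0**2)
    )
    v[:, 1] += front * (-chin + pits)
    v[:, 2] += top * ridge
    mesh.vertices = v
    landmarks = LandmarkSet(
        pog=np.array([0.0, -26.0, -3.0]),
        mf_left=np.array([-22.0, -20.0, 2.0]),
        mf_right=np.array([22.0, -20.0, 2.0]),
    )
    return mesh, landmarks


def arch_placement(slot: int, n_slots: int = 14) -> RigidTransform:
    """Rigid placement of arch slot ``slot`` (0 = left second molar) on an
    elliptical arch above the mandible slab; local +X maps to the outward
    (buccal) direction, +Z stays vertical."""
    alpha = np.deg2rad(-75.0 + 150.0 * slot / (n_slots - 1))
    a, b = 25.0, 18.0
    pos = np.array([a * np.sin(alpha), -b * np.cos(alpha), 14.0])
    buccal = np.array([np.sin(alpha) / a, -np.cos(alpha) / b, 0.0])
    buccal /= np.linalg.norm(buccal)
    up = np.array([0.0, 0.0, 1.0])
    mesial = np.cross(up, buccal)
    rot = np.column_stack([buccal, mesial, up])
    return RigidTransform(rot, pos)


def _add_noise(mesh: trimesh.Trimesh, sd: float, rng: np.random.Generator) -> None:
    if sd <= 0:
        return
    normals = np.asarray(mesh.vertex_normals, dtype=float)
    mesh.vertices = (
        np.asarray(mesh.vertices, dtype=float)
        + rng.normal(0.0, sd, size=len(mesh.vertices))[:, None] * normals
    )


def _random_case_transform(rng: np.random.Generator) -> RigidTransform:
    angles = rng.uniform(-10.0, 10.0, size=3)
    shift = rng.uniform(-10.0, 10.0, size=3)
    from .geometry import EulerAngles, rotation_from_euler

    rot = rotation_from_euler(EulerAngles(*angles))
    return RigidTransform(rot, shift)


def make_case(
    spec: CohortSpec,
    patient_index: int,
    out_dir: str | Path,
) -> tuple[Path, pd.DataFrame]:
    """Emit one patient's record set (T1/T2 mandible + landmarks, 14
    predicted and achieved crowns, manifest JSON) and return the manifest
    path plus the drawn ground-truth prediction differences.

    The per-tooth displacement is injected about the frame of the cropped
    predicted crown, in the prediction-difference sign convention: a drawn
    vector g means the measurement stage should recover exactly g.
    """
    out_dir = Path(out_dir)
    patient_id = f"SYN{patient_index:02d}"
    case_dir = out_dir / patient_id
    case_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([int(spec.seed) % (2**31), 7919 + patient_index])

    mandible, lms_t1 = make_mandible(seed=int(spec.seed) % (2**31))
    case_t = _random_case_transform(rng)
    t2_mandible = mandible.copy()
    t2_mandible.vertices = case_t.apply(np.asarray(mandible.vertices, float))
    _add_noise(t2_mandible, spec.noise_sd, rng)
    lms_t2 = LandmarkSet(
        pog=case_t.apply(lms_t1.pog),
        mf_left=case_t.apply(lms_t1.mf_left),
        mf_right=case_t.apply(lms_t1.mf_right),
    )
    write_stl(mandible, case_dir / "t1_mandible.stl")
    write_stl(t2_mandible, case_dir / "t2_mandible.stl")
    write_landmarks(lms_t1, case_dir / "t1_landmarks.csv")
    write_landmarks(lms_t2, case_dir / "t2_landmarks.csv")

    teeth_entries = []
    truth_rows = []
    for slot, fdi in enumerate(ARCH_FDI):
        ttype = tooth_type_of(fdi)
        crown, (occ, buc) = make_crown(
            ttype, seed=int(rng.integers(0, 2**31))
        )
        g = rng.normal(spec.mu[ttype], spec.sigma[ttype])
        # frame of the cropped predicted crown, in crown coordinates
        frame0 = build_tooth_frame(crown, occ, buc)
        cropped = crop_occlusal_third(crown, frame0)
        frame = build_tooth_frame(cropped, occ, buc)
        t_g = transform_from_six(SixMeasures(*g))
        displace = frame.to_world.compose(t_g.invert()).compose(frame.to_local)
        achieved = crown.copy()
        achieved.vertices = displace.apply(np.asarray(crown.vertices, float))

        place = arch_placement(slot)
        predicted_world = crown.copy()
        predicted_world.vertices = place.apply(np.asarray(crown.vertices, float))
        achieved_t2 = achieved.copy()
        achieved_t2.vertices = case_t.compose(place).apply(
            np.asarray(achieved.vertices, float)
        )
        _add_noise(achieved_t2, spec.noise_sd, rng)

        pred_path = case_dir / f"predicted_{fdi}.stl"
        achv_path = case_dir / f"achieved_{fdi}.stl"
        write_stl(predicted_world, pred_path)
        write_stl(achieved_t2, achv_path)
        teeth_entries.append({
            "fdi": fdi,
            "predicted": pred_path.name,
            "achieved": achv_path.name,
            "occlusal_dir": (place.rotation @ occ).tolist(),
            "buccal_dir": (place.rotation @ buc).tolist(),
        })
        truth_rows.append({
            "patient_id": patient_id, "fdi": fdi, "tooth_type": ttype,
            "phi_deg": g[0], "theta_deg": g[1], "psi_deg": g[2],
            "x_mm": g[3], "y_mm": g[4], "z_mm": g[5],
        })

    manifest = {
        "patient_id": patient_id,
        "units": "mm",
        "t1_mandible": "t1_mandible.stl",
        "t2_mandible": "t2_mandible.stl",
        "t1_landmarks": "t1_landmarks.csv",
        "t2_landmarks": "t2_landmarks.csv",
        "teeth": teeth_entries,
    }
    manifest_path = case_dir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest_path, pd.DataFrame(truth_rows)


def simulate_cohort_table(spec: CohortSpec) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Draw a tooth-level measure table directly from N(mu_type, sigma_type),
    without meshes — same grouping structure as the measurement output.

    Returns the table and the ground-truth means per tooth type.
    """
    rng = np.random.default_rng([int(spec.seed) % (2**31), 104729])
    rows = []
    for p in range(spec.n_patients):
        patient_id = f"SYN{p:02d}"
        for fdi in ARCH_FDI:
            ttype = tooth_type_of(fdi)
            g = rng.normal(spec.mu[ttype], spec.sigma[ttype])
            rows.append({
                "patient_id": patient_id, "fdi": fdi, "tooth_type": ttype,
                "phi_deg": g[0], "theta_deg": g[1], "psi_deg": g[2],
                "x_mm": g[3], "y_mm": g[4], "z_mm": g[5],
            })
    return pd.DataFrame(rows), {t: spec.mu[t].copy() for t in spec.mu}
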
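"""Per-tooth prediction-difference measurement.

Each tooth's achieved (post-treatment) crown is rigidly fitted onto its
predicted crown inside the predicted tooth's local anatomical frame, whose
origin sits at the predicted crown's bounding-box centre — anchoring the
origin there removes the rotation/translation coupling a rigid transform
has about an arbitrary origin.  The fitted transform is the change
required to carry the achieved pose onto the predicted one, so an
achieved pose displaced positively along any measure yields a *negative*
prediction difference on that measure, and vice versa.

Decomposition into (Phi, Theta, Psi, X, Y, Z): Phi = rotation about local
Z (mesiodistal rotation), Theta = about Y (buccolingual torque), Psi =
about X (mesiodistal tip); X/Y/Z = buccolingual / mesiodistal /
occlusogingival translations.  Differences beyond 0.5 mm (linear) or 2
degrees (angular) are flagged clinically relevant (ABO-OGS thresholds,
strict inequality).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

from .crownprep import (
    ToothFrame,
    build_tooth_frame,
    crop_occlusal_third,
    occlusal_plane_z,
    to_local_mesh,
    tooth_type_of,
)
from .geometry import RigidTransform, SixMeasures, six_measures
from .meshio import CaseManifest, read_stl
from .registration import (
    DEFAULT_RMS_GATE,
    CaseSuperimposition,
    IcpParams,
    RegistrationResult,
    icp,
    superimpose_case,
)

__all__ = [
    "RelevanceFlags",
    "ToothMeasure",
    "ToothFailure",
    "DEFAULT_LINEAR_GATE",
    "DEFAULT_ANGULAR_GATE",
    "classify_relevance",
    "measure_prediction_difference",
    "measure_case",
]

DEFAULT_LINEAR_GATE = 0.5   # mm
DEFAULT_ANGULAR_GATE = 2.0  # degrees


@dataclass(frozen=True)
class RelevanceFlags:
    phi: bool
    theta: bool
    psi: bool
    x: bool
    y: bool
    z: bool

    def as_dict(self) -> dict[str, bool]:
        return {k: getattr(self, k) for k in ("phi", "theta", "psi", "x", "y", "z")}


@dataclass(frozen=True)
class ToothMeasure:
    patient_id: str
    fdi: int
    tooth_type: str
    measures: SixMeasures
    rms: float
    accepted: bool
    relevant: RelevanceFlags
    registration: RegistrationResult | None = None


@dataclass(frozen=True)
class ToothFailure:
    patient_id: str
    fdi: int
    stage: str
    reason: str


def classify_relevance(
    m: SixMeasures,
    linear_gate: float = DEFAULT_LINEAR_GATE,
    angular_gate: float = DEFAULT_ANGULAR_GATE,
) -> RelevanceFlags:
    """Clinical-relevance flags: strictly larger than 0.5 mm / 2 degrees in
    magnitude (values exactly at the gate are not flagged)."""
    if linear_gate <= 0 or angular_gate <= 0:
        raise ValueError("gates must be positive")
    return RelevanceFlags(
        phi=abs(m.phi) > angular_gate,
        theta=abs(m.theta) > angular_gate,
        psi=abs(m.psi) > angular_gate,
        x=abs(m.x) > linear_gate,
        y=abs(m.y) > linear_gate,
        z=abs(m.z) > linear_gate,
    )


def _coarse_grid_init(
    achieved_local: trimesh.Trimesh,
    predicted_local: trimesh.Trimesh,
    params: IcpParams,
    rms_gate: float,
) -> RegistrationResult:
    """Fallback search over a small pose grid when the identity-initialised
    fit stalls in a poor minimum (0.5 mm / 5 degree steps, one level)."""
    from .geometry import EulerAngles, rotation_from_euler

    best: RegistrationResult | None = None
    steps_deg = (-5.0, 0.0, 5.0)
    steps_mm = (-0.5, 0.0, 0.5)
    for phi in steps_deg:
        for dx in steps_mm:
            for dy in steps_mm:
                init = RigidTransform(
                    rotation_from_euler(EulerAngles(phi, 0.0, 0.0)),
                    np.array([dx, dy, 0.0]),
                )
                res = icp(achieved_local, predicted_local, init=init,
                          params=params, rms_gate=rms_gate)
                if best is None or res.rms < best.rms:
                    best = res
    assert best is not None
    return best


def measure_prediction_difference(
    achieved: trimesh.Trimesh,
    predicted: trimesh.Trimesh,
    frame: ToothFrame,
    params: IcpParams = IcpParams(),
    rms_gate: float = DEFAULT_RMS_GATE,
    linear_gate: float = DEFAULT_LINEAR_GATE,
    angular_gate: float = DEFAULT_ANGULAR_GATE,
    patient_id: str = "",
    fdi: int = 0,
) -> ToothMeasure:
    """Six-measure prediction difference between crowns already cropped to
    their occlusal thirds and expressed in a common case frame.

    ``frame`` must be the predicted crown's anatomical frame.  Both crowns
    are re-expressed in that frame (predicted bounding-box centre at the
    origin), the achieved crown is ICP-fitted onto the predicted one, and
    the fitted transform is decomposed into the six signed measures.
    """
    achieved_local = to_local_mesh(achieved, frame)
    predicted_local = to_local_mesh(predicted, frame)
    res = icp(achieved_local, predicted_local, init=None,
              params=params, rms_gate=rms_gate)
    if res.rms > 10.0 * rms_gate:
        grid = _coarse_grid_init(achieved_local, predicted_local, params, rms_gate)
        if grid.rms < res.rms:
            res = grid
    m = six_measures(res.transform)
    return ToothMeasure(
        patient_id=patient_id,
        fdi=fdi,
        tooth_type=tooth_type_of(fdi) if fdi else "",
        measures=m,
        rms=res.rms,
        accepted=res.accepted,
        relevant=classify_relevance(m, linear_gate, angular_gate),
        registration=res,
    )


def measure_case(
    case: CaseManifest,
    params: IcpParams = IcpParams(),
    superimposition: CaseSuperimposition | None = None,
    rms_gate: float = DEFAULT_RMS_GATE,
    linear_gate: float = DEFAULT_LINEAR_GATE,
    angular_gate: float = DEFAULT_ANGULAR_GATE,
    fit_margin: float = 2.0,
) -> tuple[list[ToothMeasure], list[ToothFailure]]:
    """Measure every tooth of a case: superimpose T2 onto T1, carry the
    achieved crowns into the predicted frame, crop both crowns to their
    occlusal thirds and fit tooth by tooth.

    The moving (achieved) crown is cropped to its occlusal third; the
    fixed fit target is the predicted crown cropped ``fit_margin`` mm
    *deeper*, so that every moving point keeps a true counterpart on the
    fixed surface even when the achieved pose is displaced — a one-sided
    crop mismatch at the cut would otherwise pull the fit toward the rim.
    The local frame (and hence the translation origin) is still that of
    the predicted crown's occlusal third.

    Per-tooth failures are collected, not fatal to the case.  Raises if the
    mandibular superimposition itself is rejected by the RMS gate.
    """
    if superimposition is None:
        superimposition = superimpose_case(case, rms_gate=rms_gate)
    if not superimposition.accepted:
        raise RuntimeError(
            f"case {case.patient_id}: mandibular superimposition rejected "
            f"(RMS {superimposition.fine.rms:.4f} > gate {rms_gate}); "
            "refusing to measure teeth"
        )
    carry = superimposition.transform
    measures: list[ToothMeasure] = []
    failures: list[ToothFailure] = []
    for tooth in case.teeth:
        try:
            predicted = read_stl(tooth.predicted)
            achieved = read_stl(tooth.achieved)
        except Exception as exc:
            failures.append(ToothFailure(case.patient_id, tooth.fdi, "load", str(exc)))
            continue
        try:
            achieved.vertices = carry.apply(np.asarray(achieved.vertices, dtype=float))
            frame0 = build_tooth_frame(predicted, tooth.occlusal_dir, tooth.buccal_dir)
            predicted_c = crop_occlusal_third(predicted, frame0)
            plane = occlusal_plane_z(predicted, frame0)
            predicted_fit = crop_occlusal_third(
                predicted, frame0, plane_z=plane - fit_margin
            )
            achieved_c = crop_occlusal_third(achieved, frame0)
            frame = build_tooth_frame(predicted_c, tooth.occlusal_dir, tooth.buccal_dir)
            measures.append(measure_prediction_difference(
                achieved_c, predicted_fit, frame, params=params, rms_gate=rms_gate,
                linear_gate=linear_gate, angular_gate=angular_gate,
                patient_id=case.patient_id, fdi=tooth.fdi,
            ))
        except Exception as exc:
            failures.append(
                ToothFailure(case.patient_id, tooth.fdi, "measure", str(exc))
            )
    return measures, failures


def measures_to_records(measures: list[ToothMeasure]) -> list[dict]:
    """Flatten ToothMeasures into CSV-ready records."""
    records = []
    for tm in measures:
        m = tm.measures
        rec = {
            "patient_id": tm.patient_id,
            "fdi": tm.fdi,
            "tooth_type": tm.tooth_type,
            "phi_deg": m.phi,
            "theta_deg": m.theta,
            "psi_deg": m.psi,
            "x_mm": m.x,
            "y_mm": m.y,
            "z_mm": m.z,
            "rms_mm": tm.rms,
            "accepted": tm.accepted,
        }
        rec.update({f"relevant_{k}": v for k, v in tm.relevant.as_dict().items()})
        records.append(rec)
    return records
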
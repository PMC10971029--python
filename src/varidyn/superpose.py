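"""Rigid-body superposition (Kabsch) and RMSD series.

Every frame of an ensemble is least-squares fitted onto a reference
conformation using a *fitting* selection (conventionally the C-alpha atoms
of the chain that was held fixed during simulation), and RMSD is then
reported on a separate *reporting* selection (conventionally the mobile
regulatory chain). Reflections are excluded: the fitted transform is always
a proper rotation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .structure_io import Selection, Structure, TrajectoryEnsemble

__all__ = ["RigidTransform", "RmsdSeries", "kabsch_fit", "superpose_ensemble", "rmsd_series"]

_DEGENERACY_TOL = 1e-8


@dataclass
class RigidTransform:
    """A proper rigid motion x -> R x + t (rotation then translation, A)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation length 3")
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("reflection is not a valid rigid transform")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Apply to an (..., 3) coordinate array."""
        return np.asarray(coords) @ self.rotation.T + self.translation

    def to_json(self) -> dict:
        return {"rotation": self.rotation.tolist(), "translation": self.translation.tolist()}


@dataclass
class RmsdSeries:
    """Per-frame RMSD [A] of a reporting selection against a reference."""

    values: np.ndarray
    fit_selection: Selection | None
    report_selection: Selection
    reference_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("RMSD values must be non-negative")


def kabsch_fit(mobile: np.ndarray, reference: np.ndarray) -> RigidTransform:
    """Least-squares rigid fit of ``mobile`` onto ``reference`` (Kabsch, SVD).

    Both inputs are N x 3 with matched atom correspondence, N >= 3 and not
    collinear. The returned transform minimizes the RMSD of the transformed
    mobile coordinates to the reference; the rotation is proper (det +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must be matching N x 3 arrays")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError(f"at least 3 points required for a rigid fit, got {n}")
    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    mc = mobile - cm
    rc = reference - cr
    for name, pts in (("mobile", mc), ("reference", rc)):
        s = np.linalg.svd(pts, compute_uv=False)
        if s[1] <= _DEGENERACY_TOL * max(1.0, s[0]):
            raise ValueError(f"{name} point set is degenerate (collinear); rotation is not unique")
    # cross-covariance: rows of mc map onto rows of rc
    cov = mc.T @ rc
    u, _, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = cr - rot @ cm
    return RigidTransform(rotation=rot, translation=trans)


def superpose_ensemble(
    ensemble: TrajectoryEnsemble,
    reference: Structure,
    fit_selection: Selection,
) -> TrajectoryEnsemble:
    """Fit every frame onto the reference using the fitting selection.

    Each frame gets its own Kabsch fit on the selected atoms; the resulting
    rigid transform is applied to *all* atoms of the frame. The selection
    must resolve to the same atom count on ensemble and reference.
    """
    idx = fit_selection.resolved_indices
    if idx.size and idx.max() >= min(ensemble.n_atoms, reference.n_atoms):
        raise ValueError("fit selection indices exceed atom count of ensemble or reference")
    ref_xyz = reference.coordinates[idx]
    if ref_xyz.shape[0] != idx.size:
        raise ValueError("fit selection resolves to different atom counts on ensemble and reference")
    out = np.empty_like(ensemble.frames)
    for t in range(ensemble.n_frames):
        tf = kabsch_fit(ensemble.frames[t, idx], ref_xyz)
        out[t] = tf.apply(ensemble.frames[t])
    return replace(ensemble, frames=out)


def rmsd_series(
    ensemble: TrajectoryEnsemble,
    reference: Structure,
    report_selection: Selection,
    fit_selection: Selection | None = None,
) -> RmsdSeries:
    """Per-frame RMSD on the reporting selection (no re-fitting here).

    The ensemble is assumed already superposed; pass ``fit_selection`` only
    to record provenance.
    """
    idx = report_selection.resolved_indices
    if idx.size == 0:
        raise ValueError("empty reporting selection")
    diff = ensemble.frames[:, idx, :] - reference.coordinates[idx]
    values = np.sqrt(np.mean(np.sum(diff * diff, axis=2), axis=1))
    return RmsdSeries(
        values=values,
        fit_selection=fit_selection,
        report_selection=report_selection,
        reference_label=ensemble.label,
    )
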
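"""Superposition and inter-domain rotation geometry.

The central construction: every trajectory frame is first superposed on the
initial structure using the alpha-tubulin (TUBA) core Calpha atoms, which
removes global rigid motion and mimics the experimental anchoring of the dimer
by its TUBA base.  What remains is the *relative* motion of beta-tubulin
(TUBB), quantified either as a Calpha-RMSD or as a rotation that is split into

* **twist** (chi): the signed rotation about the dimer axis, and
* **tilt** (theta): the non-negative swing of that axis away from its
  reference direction,

exactly the two angular observables diffracted X-ray tracking reports for a
molecule anchored upright on a substrate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from tubudyn.io import AngularTrack, DimerTrajectory, ResidueSelection

__all__ = [
    "SuperpositionResult",
    "TwistTiltSeries",
    "kabsch_superpose",
    "relative_rmsd_series",
    "rmsf",
    "swing_twist_decompose",
    "twist_tilt_series",
]


@dataclass
class SuperpositionResult:
    """Optimal rigid transform ``x -> rotation @ x + translation`` mapping the
    mobile point set onto the reference, with the residual RMSD."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd_after: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> SuperpositionResult:
    """Least-squares optimal rigid superposition (Kabsch algorithm).

    Finds the proper rotation ``R`` and translation ``t`` minimising the
    (weighted) RMSD between ``R @ mobile + t`` and ``reference``.  Requires at
    least three non-collinear points in each set.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must both have shape (n, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 points")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or (w < 0).any() or w.sum() == 0:
            raise ValueError("weights must be non-negative with positive sum")
    wsum = w.sum()
    cm = (w[:, None] * mobile).sum(axis=0) / wsum
    cr = (w[:, None] * reference).sum(axis=0) / wsum
    m = mobile - cm
    r = reference - cr
    for label, pts in (("mobile", m), ("reference", r)):
        if np.linalg.matrix_rank(pts, tol=1e-9 * max(1.0, np.abs(pts).max())) < 2:
            raise ValueError(f"degenerate (collinear) {label} configuration")
    h = (w[:, None] * m).T @ r  # 3x3 cross-covariance
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = cr - rot @ cm
    resid = mobile @ rot.T + t - reference
    rmsd = float(np.sqrt((w * (resid**2).sum(axis=1)).sum() / wsum))
    return SuperpositionResult(rotation=rot, translation=t, rmsd_after=rmsd)


def _core_ca(traj: DimerTrajectory, selection: ResidueSelection, role: str) -> np.ndarray:
    idx = traj.topology.select(role, resid_range=selection.core[role], atom_names=["CA"])
    if len(idx) == 0:
        raise ValueError(f"selection yields no core CA atoms for role {role!r}")
    return idx


def relative_rmsd_series(traj: DimerTrajectory, selection: ResidueSelection) -> np.ndarray:
    """Per-frame Calpha-RMSD of the TUBB core after fitting each frame's TUBA
    core onto frame 0 (no second fit on TUBB).

    This *relative* RMSD measures the displacement of beta-tubulin with respect
    to alpha-tubulin and can greatly exceed the within-domain RMSD.
    """
    idx_a = _core_ca(traj, selection, "TUBA")
    idx_b = _core_ca(traj, selection, "TUBB")
    ref = traj.coords[0]
    out = np.empty(traj.n_frames)
    for i, frame in enumerate(traj.coords):
        sup = kabsch_superpose(frame[idx_a], ref[idx_a])
        moved_b = sup.apply(frame[idx_b])
        out[i] = float(np.sqrt(((moved_b - ref[idx_b]) ** 2).sum(axis=1).mean()))
    return out


def rmsf(traj: DimerTrajectory, selection: ResidueSelection) -> pd.DataFrame:
    """Per-residue Calpha root-mean-square fluctuation about the time-average
    position, with each chain fitted on its own core.

    Returns a DataFrame with columns ``role``, ``resid``, ``rmsf``.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    rows = []
    for role in ("TUBA", "TUBB"):
        idx = _core_ca(traj, selection, role)
        ref = traj.coords[0][idx]
        aligned = np.empty((traj.n_frames, len(idx), 3))
        for i, frame in enumerate(traj.coords):
            sup = kabsch_superpose(frame[idx], ref)
            aligned[i] = sup.apply(frame[idx])
        mean = aligned.mean(axis=0)
        fluct = np.sqrt(((aligned - mean) ** 2).sum(axis=2).mean(axis=0))
        resids = traj.topology.resids[idx]
        rows.append(pd.DataFrame({"role": role, "resid": resids, "rmsf": fluct}))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# swing--twist decomposition
# ---------------------------------------------------------------------------


def swing_twist_decompose(
    rotation: np.ndarray, axis: np.ndarray
) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Split a rotation into twist about ``axis`` and a swing of the axis.

    Returns ``(twist_deg, tilt_deg, r_twist, r_swing)`` with the exact
    recomposition ``rotation = r_swing @ r_twist``.  The twist is signed
    (right-handed about ``axis``) in (-180, 180]; the tilt is the swing
    magnitude in [0, 180].  Computed via the quaternion projection method:
    the twist quaternion is the normalised projection of the rotation
    quaternion onto the (1, axis) plane, which is numerically stable and
    exactly invertible for tilt < 180 degrees.
    """
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("axis must be a non-zero vector")
    axis = axis / norm
    rot = Rotation.from_matrix(np.asarray(rotation, dtype=float))
    x, y, z, w = rot.as_quat()
    v = np.array([x, y, z])
    d = float(v @ axis)
    tw_norm = np.hypot(w, d)
    if tw_norm < 1e-12:
        # 180-degree swing exactly perpendicular to the axis: twist undefined,
        # take it as zero.
        r_twist = Rotation.identity()
        twist = 0.0
    else:
        r_twist = Rotation.from_quat(
            np.array([d * axis[0], d * axis[1], d * axis[2], w]) / tw_norm
        )
        twist = 2.0 * np.arctan2(d, w)
        # map to (-pi, pi]
        twist = float(np.arctan2(np.sin(twist), np.cos(twist)))
    r_swing = rot * r_twist.inv()
    tilt = float(r_swing.magnitude())
    return (
        float(np.degrees(twist)),
        float(np.degrees(tilt)),
        r_twist.as_matrix(),
        r_swing.as_matrix(),
    )


@dataclass
class TwistTiltSeries:
    """Per-frame twist (signed, about the dimer axis) and tilt (non-negative)
    angles of the TUBB core relative to frame 0, in degrees.

    ``axis`` is the dimer axis expressed in the reference (frame 0) system.
    Twist values are unwrapped over time so that the series is continuous.
    """

    twist: np.ndarray
    tilt: np.ndarray
    axis: np.ndarray
    frame_interval: float
    run_id: str = "run"

    def __post_init__(self) -> None:
        self.twist = np.asarray(self.twist, dtype=float)
        self.tilt = np.asarray(self.tilt, dtype=float)
        if self.twist.shape != self.tilt.shape:
            raise ValueError("twist and tilt must have the same length")
        if (self.tilt < -1e-9).any():
            raise ValueError("tilt angles must be non-negative")

    def to_angular_track(self, track_id: str | None = None) -> AngularTrack:
        """Export as an :class:`AngularTrack` (tilt -> theta, twist -> chi) so
        MD-derived angles feed the same MSD pipeline as DXT tracks."""
        return AngularTrack(
            track_id=track_id or self.run_id,
            theta=self.tilt.copy(),
            chi=self.twist.copy(),
            frame_interval=self.frame_interval,
        )


def twist_tilt_series(
    traj: DimerTrajectory,
    selection: ResidueSelection,
    axis: np.ndarray | None = None,
) -> TwistTiltSeries:
    """Twist/tilt angles of the TUBB core per frame, relative to frame 0.

    Each frame's TUBA core is superposed on frame 0; the Kabsch rotation that
    then maps the frame-0 TUBB core onto the frame's TUBB core is decomposed
    into twist about the dimer axis and tilt of that axis.  By default the
    dimer axis is the unit vector from the TUBA-core to the TUBB-core Calpha
    centroid in frame 0 (the anchored vertical axis of the DXT geometry),
    pointing TUBA -> TUBB.
    """
    idx_a = _core_ca(traj, selection, "TUBA")
    idx_b = _core_ca(traj, selection, "TUBB")
    ref = traj.coords[0]
    if axis is None:
        axis = ref[idx_b].mean(axis=0) - ref[idx_a].mean(axis=0)
    axis = np.asarray(axis, dtype=float)
    if np.linalg.norm(axis) == 0:
        raise ValueError("degenerate dimer axis")
    axis = axis / np.linalg.norm(axis)
    twist = np.empty(traj.n_frames)
    tilt = np.empty(traj.n_frames)
    for i, frame in enumerate(traj.coords):
        sup_a = kabsch_superpose(frame[idx_a], ref[idx_a])
        moved_b = sup_a.apply(frame[idx_b])
        sup_b = kabsch_superpose(ref[idx_b], moved_b)
        tw, ti, _, _ = swing_twist_decompose(sup_b.rotation, axis)
        twist[i] = tw
        tilt[i] = ti
    twist = np.degrees(np.unwrap(np.radians(twist)))
    return TwistTiltSeries(
        twist=twist,
        tilt=tilt,
        axis=axis,
        frame_interval=traj.frame_interval,
        run_id=traj.run_id,
    )
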
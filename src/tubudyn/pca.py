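"""Principal component analysis of the relative TUBB-core motion.

After every frame is fitted on the TUBA core of the shared initial structure,
the Calpha coordinates of the TUBB core form a 3N-dimensional point per frame.
The covariance of these points, pooled over all runs, is eigendecomposed; the
leading eigenvectors are the dominant collective motions of beta-tubulin
relative to alpha-tubulin (twist- and tilt-like patterns for the tubulin
dimer), and each eigenvalue divided by the total variance is that mode's
*contribution ratio*.  Projecting the frames onto the PC1-PC2 plane and
histogramming gives the structural occupancy map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from tubudyn.geometry import kabsch_superpose
from tubudyn.io import DimerTrajectory, ResidueSelection

__all__ = [
    "OccupancyGrid",
    "PCAResult",
    "occupancy_map",
    "project_mode_vectors",
    "relative_motion_pca",
]


@dataclass
class OccupancyGrid:
    """Normalised 2-D histogram of PC1/PC2 projections."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    fractions: np.ndarray  # shape (nx, ny), sums to 1

    @property
    def peak_fraction(self) -> float:
        """The largest bin fraction (the map's 'presence frequency' peak)."""
        return float(self.fractions.max())

    def to_frame(self) -> pd.DataFrame:
        xc = 0.5 * (self.x_edges[:-1] + self.x_edges[1:])
        yc = 0.5 * (self.y_edges[:-1] + self.y_edges[1:])
        xx, yy = np.meshgrid(xc, yc, indexing="ij")
        return pd.DataFrame(
            {"pc1_center": xx.ravel(), "pc2_center": yy.ravel(), "fraction": self.fractions.ravel()}
        )


@dataclass
class PCAResult:
    """Eigendecomposition of the pooled relative-motion covariance.

    ``eigenvectors`` has unit-norm columns of length 3N; ``projections`` holds
    the per-frame scores on PC1 and PC2 with a ``run_id`` label; contribution
    ratios are eigenvalues over total variance and sum to 1.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    contribution_ratios: np.ndarray
    projections: pd.DataFrame = field(repr=False)
    mean: np.ndarray = field(repr=False)
    atom_indices: np.ndarray = field(repr=False)
    occupancy: OccupancyGrid | None = None

    @property
    def total_variance(self) -> float:
        return float(self.eigenvalues.sum())


def _fitted_tubb_coords(
    trajs: Sequence[DimerTrajectory], selection: ResidueSelection
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """TUBA-core-fit all frames of all runs to the first run's frame 0 and
    return the flattened TUBB-core Calpha coordinates."""
    trajs = list(trajs)
    if not trajs:
        raise ValueError("need at least one trajectory")
    top0 = trajs[0].topology
    idx_a = top0.select("TUBA", selection.core["TUBA"], atom_names=["CA"])
    idx_b = top0.select("TUBB", selection.core["TUBB"], atom_names=["CA"])
    if len(idx_a) == 0 or len(idx_b) == 0:
        raise ValueError("selection yields no core CA atoms")
    ref = trajs[0].coords[0]
    rows = []
    run_ids = []
    for traj in trajs:
        if traj.topology.n_atoms != top0.n_atoms:
            raise ValueError("all runs must share one topology")
        for frame in traj.coords:
            sup = kabsch_superpose(frame[idx_a], ref[idx_a])
            rows.append(sup.apply(frame[idx_b]).ravel())
            run_ids.append(traj.run_id)
    return np.asarray(rows), idx_a, idx_b, run_ids


def relative_motion_pca(
    trajs: Sequence[DimerTrajectory] | DimerTrajectory,
    selection: ResidueSelection,
    occupancy_bins: int = 50,
) -> PCAResult:
    """PCA of TUBB-core Calpha motion after TUBA-core fitting.

    The principal axes are computed from the pooled frames of *all* supplied
    runs (shared axes, so different dimers project onto a common plane);
    per-frame projections keep their ``run_id``.  All stored frames enter the
    covariance, centred on the pooled mean.
    """
    if isinstance(trajs, DimerTrajectory):
        trajs = [trajs]
    x, _, idx_b, run_ids = _fitted_tubb_coords(trajs, selection)
    if x.shape[0] < 2:
        raise ValueError("PCA needs at least 2 frames in total")
    mean = x.mean(axis=0)
    xc = x - mean
    cov = xc.T @ xc / xc.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    total = evals.sum()
    ratios = evals / total if total > 0 else np.zeros_like(evals)
    scores = xc @ evecs[:, :2]
    projections = pd.DataFrame(
        {"run_id": run_ids, "pc1": scores[:, 0], "pc2": scores[:, 1]}
    )
    result = PCAResult(
        eigenvalues=evals,
        eigenvectors=evecs,
        contribution_ratios=ratios,
        projections=projections,
        mean=mean,
        atom_indices=idx_b,
    )
    result.occupancy = occupancy_map(projections[["pc1", "pc2"]].to_numpy(), occupancy_bins)
    return result


def occupancy_map(projections: np.ndarray, bins: int | Sequence[int] = 50) -> OccupancyGrid:
    """2-D histogram of (PC1, PC2) scores normalised to fractions.

    The grid spans the pooled projection extrema.  Fractions sum to 1 for any
    bin count; the peak fraction is the map's maximum presence frequency.
    """
    projections = np.asarray(projections, dtype=float)
    if projections.ndim != 2 or projections.shape[1] != 2:
        raise ValueError("projections must have shape (n, 2)")
    if not np.isfinite(projections).all():
        raise ValueError("projections must be finite")
    if isinstance(bins, int):
        if bins <= 0:
            raise ValueError("bin count must be positive")
    counts, x_edges, y_edges = np.histogram2d(
        projections[:, 0], projections[:, 1], bins=bins
    )
    return OccupancyGrid(
        x_edges=x_edges, y_edges=y_edges, fractions=counts / counts.sum()
    )


def project_mode_vectors(
    pca_result: PCAResult, mode_index: int
) -> np.ndarray:
    """Per-atom displacement 3-vectors of one principal mode, scaled by the
    square root of its eigenvalue (an RMS-amplitude-weighted motion pattern
    suitable for drawing arrows on the structure).

    ``mode_index`` is 0-based (0 -> PC1).  Returns an array of shape (N, 3)
    over the TUBB-core Calpha atoms of the analysis.
    """
    n_modes = pca_result.eigenvectors.shape[1]
    if not 0 <= mode_index < n_modes:
        raise ValueError(f"mode_index must be in [0, {n_modes - 1}]")
    vec = pca_result.eigenvectors[:, mode_index]
    amp = np.sqrt(pca_result.eigenvalues[mode_index])
    return (amp * vec).reshape(-1, 3)


def mode_vectors_frame(pca_result: PCAResult, topology, mode_index: int) -> pd.DataFrame:
    """Tabular export of a mode: residue, displacement vector and its norm
    (the norm doubles as a pseudo-B-factor for structure colouring)."""
    vecs = project_mode_vectors(pca_result, mode_index)
    resids = topology.resids[pca_result.atom_indices]
    return pd.DataFrame(
        {
            "resid": resids,
            "dx": vecs[:, 0],
            "dy": vecs[:, 1],
            "dz": vecs[:, 2],
            "norm": np.linalg.norm(vecs, axis=1),
        }
    )
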
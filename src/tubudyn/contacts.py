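"""Heavy-atom contacts at the TUBA-TUBB interface.

A residue pair (one residue per chain role) is *in contact* in a frame when
any heavy-atom pair, one atom from each residue, is strictly closer than the
cutoff (default 4.0 Angstroms; atoms at exactly the cutoff do not count).  The
contact frequency of a residue (or pair) is the fraction of frames, pooled
over all runs, in which it participates in at least one such contact.

Neighbour search uses a k-d tree; the O(N^2) all-pairs computation is kept in
the test suite as an oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from tubudyn.io import DimerTrajectory, ResidueSelection, Topology

__all__ = [
    "ContactCountSeries",
    "ContactFrequencyTable",
    "contact_count_distribution",
    "contact_frequency",
    "frame_contacts",
    "ligand_contact_frequency",
]

DEFAULT_CUTOFF = 4.0  # Angstrom, strict inequality
PBC_JUMP_THRESHOLD = 20.0  # Angstrom; inter-chain centroid jumps above this
#                           suggest a trajectory that was not made whole

#: a residue key: (chain id, 1-based residue number)
ResKey = tuple[str, int]


@dataclass
class ContactFrequencyTable:
    """Per-residue and per-residue-pair contact frequencies.

    ``per_residue`` columns: role, resid, resname, frequency (pooled 0-1) and
    one ``freq_<run_id>`` column per run.  ``per_pair`` columns: resid_a,
    resname_a, resid_b, resname_b, frequency and per-run columns, where side
    ``a`` is the first group (TUBA for interface tables).
    """

    per_residue: pd.DataFrame = field(repr=False)
    per_pair: pd.DataFrame = field(repr=False)
    n_frames: int = 0
    cutoff: float = DEFAULT_CUTOFF


@dataclass
class ContactCountSeries:
    """Per-frame count of interface residue pairs in contact, plus the
    normalised histogram over frames."""

    counts: pd.DataFrame = field(repr=False)  # columns: run_id, frame, n_contacts
    histogram: pd.DataFrame = field(repr=False)  # columns: n_contacts, fraction

    @property
    def mean_count(self) -> float:
        return float(self.counts["n_contacts"].mean())


def frame_contacts(
    coords: np.ndarray,
    topology: Topology,
    group_a: np.ndarray,
    group_b: np.ndarray,
    cutoff: float = DEFAULT_CUTOFF,
) -> set[tuple[ResKey, ResKey]]:
    """Residue pairs with any heavy-atom pair strictly closer than ``cutoff``.

    ``group_a`` and ``group_b`` are disjoint atom-index arrays; hydrogens in
    either group are ignored.  Returns pairs of residue keys
    ``((chain_a, resid_a), (chain_b, resid_b))``.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    group_a = np.asarray(group_a, dtype=int)
    group_b = np.asarray(group_b, dtype=int)
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("contact groups must be non-empty")
    if np.intersect1d(group_a, group_b).size:
        raise ValueError("contact groups must be disjoint")
    heavy = topology.heavy_mask
    ga = group_a[heavy[group_a]]
    gb = group_b[heavy[group_b]]
    if len(ga) == 0 or len(gb) == 0:
        return set()
    tree_a = cKDTree(coords[ga])
    tree_b = cKDTree(coords[gb])
    neighbour_lists = tree_a.query_ball_tree(tree_b, r=cutoff)
    chains, resids = topology.chain_ids, topology.resids
    out: set[tuple[ResKey, ResKey]] = set()
    for ia, neighbours in enumerate(neighbour_lists):
        if not neighbours:
            continue
        pa = coords[ga[ia]]
        key_a = (str(chains[ga[ia]]), int(resids[ga[ia]]))
        for ib in neighbours:
            # query_ball_tree is inclusive of r; the contact definition is strict
            diff = pa - coords[gb[ib]]
            if diff @ diff < cutoff**2:
                out.add((key_a, (str(chains[gb[ib]]), int(resids[gb[ib]]))))
    return out


def _interface_groups(
    topology: Topology, selection: ResidueSelection
) -> tuple[np.ndarray, np.ndarray]:
    groups = []
    for role in ("TUBA", "TUBB"):
        rng = selection.interface_range(role)
        groups.append(topology.select(role, resid_range=rng, heavy_only=True))
    return groups[0], groups[1]


def _validate_pbc(traj: DimerTrajectory) -> None:
    top = traj.topology
    cents = []
    for role in ("TUBA", "TUBB"):
        idx = np.flatnonzero(top.role_of(role))
        cents.append(traj.coords[:, idx].mean(axis=1))
    sep = np.linalg.norm(cents[0] - cents[1], axis=1)
    if len(sep) > 1 and np.abs(np.diff(sep)).max() > PBC_JUMP_THRESHOLD:
        warnings.warn(
            f"inter-chain centroid separation jumps by more than "
            f"{PBC_JUMP_THRESHOLD} A between frames of run {traj.run_id!r}; "
            "the trajectory may not be PBC-whole",
            stacklevel=3,
        )


def _check_shared_topology(trajs: Sequence[DimerTrajectory]) -> Topology:
    if not trajs:
        raise ValueError("need at least one trajectory")
    top0 = trajs[0].topology
    for traj in trajs:
        if traj.topology.n_atoms != top0.n_atoms or not np.array_equal(
            traj.topology.resids, top0.resids
        ):
            raise ValueError("inconsistent topologies across runs")
    return top0


def _iter_interface_contacts(
    trajs: Sequence[DimerTrajectory],
    selection: ResidueSelection,
    cutoff: float,
):
    top0 = _check_shared_topology(trajs)
    ga, gb = _interface_groups(top0, selection)
    for traj in trajs:
        _validate_pbc(traj)
        for frame_no, frame in enumerate(traj.coords):
            yield traj.run_id, frame_no, frame_contacts(frame, top0, ga, gb, cutoff)


def _role_and_name(topology: Topology) -> dict[ResKey, tuple[str, str]]:
    """Map every (chain, resid) key to its (role, resname)."""
    out: dict[ResKey, tuple[str, str]] = {}
    for chain, resid, resname in zip(
        topology.chain_ids, topology.resids, topology.resnames
    ):
        key = (str(chain), int(resid))
        if key not in out:
            role = topology.roles.get(str(chain), str(chain))
            out[key] = (role, str(resname))
    return out


def _frequency_rows(
    hits: dict, run_ids: list[str], frames_per_run: dict[str, int]
) -> list[dict]:
    n_total = sum(frames_per_run.values())
    rows = []
    for key in sorted(hits):
        per_run = hits[key]
        row = {"_key": key, "frequency": sum(per_run.values()) / n_total}
        for rid in run_ids:
            row[f"freq_{rid}"] = per_run[rid] / frames_per_run[rid]
        rows.append(row)
    return rows


def contact_frequency(
    trajs: Sequence[DimerTrajectory] | DimerTrajectory,
    selection: ResidueSelection,
    cutoff: float = DEFAULT_CUTOFF,
) -> ContactFrequencyTable:
    """Interface contact frequencies pooled over runs and per run.

    A residue's frequency counts frames in which it participates in at least
    one interface contact; the pair table preserves the full per-pair
    information.  The pooled denominator is the total frame count of all runs.
    """
    if isinstance(trajs, DimerTrajectory):
        trajs = [trajs]
    trajs = list(trajs)
    run_ids = [t.run_id for t in trajs]
    frames_per_run = dict.fromkeys(run_ids, 0)
    pair_hits: dict[tuple[ResKey, ResKey], dict[str, int]] = {}
    res_hits: dict[ResKey, dict[str, int]] = {}
    for run_id, _, pairs in _iter_interface_contacts(trajs, selection, cutoff):
        frames_per_run[run_id] += 1
        seen_res = set()
        for ka, kb in pairs:
            pair_hits.setdefault((ka, kb), dict.fromkeys(run_ids, 0))[run_id] += 1
            seen_res.update((ka, kb))
        for key in seen_res:
            res_hits.setdefault(key, dict.fromkeys(run_ids, 0))[run_id] += 1
    info = _role_and_name(trajs[0].topology)

    res_rows = []
    for row in _frequency_rows(res_hits, run_ids, frames_per_run):
        key = row.pop("_key")
        role, resname = info[key]
        res_rows.append({"role": role, "resid": key[1], "resname": resname, **row})
    pair_rows = []
    for row in _frequency_rows(pair_hits, run_ids, frames_per_run):
        ka, kb = row.pop("_key")
        pair_rows.append(
            {
                "resid_a": ka[1],
                "resname_a": info[ka][1],
                "resid_b": kb[1],
                "resname_b": info[kb][1],
                **row,
            }
        )
    res_cols = ["role", "resid", "resname", "frequency"] + [f"freq_{r}" for r in run_ids]
    pair_cols = ["resid_a", "resname_a", "resid_b", "resname_b", "frequency"] + [
        f"freq_{r}" for r in run_ids
    ]
    return ContactFrequencyTable(
        per_residue=pd.DataFrame(res_rows, columns=res_cols),
        per_pair=pd.DataFrame(pair_rows, columns=pair_cols),
        n_frames=sum(frames_per_run.values()),
        cutoff=cutoff,
    )


def contact_count_distribution(
    trajs: Sequence[DimerTrajectory] | DimerTrajectory,
    selection: ResidueSelection,
    cutoff: float = DEFAULT_CUTOFF,
) -> ContactCountSeries:
    """Per-frame interface residue-pair counts and their normalised histogram.

    A shift of the histogram towards lower counts signals weakened interface
    interactions and hence enhanced relative mobility.
    """
    if isinstance(trajs, DimerTrajectory):
        trajs = [trajs]
    rows = [
        {"run_id": run_id, "frame": frame_no, "n_contacts": len(pairs)}
        for run_id, frame_no, pairs in _iter_interface_contacts(list(trajs), selection, cutoff)
    ]
    counts = pd.DataFrame(rows, columns=["run_id", "frame", "n_contacts"])
    hist = (
        counts["n_contacts"].value_counts(normalize=True).sort_index().rename("fraction")
    )
    histogram = hist.reset_index().rename(columns={"index": "n_contacts"})
    return ContactCountSeries(counts=counts, histogram=histogram)


def ligand_contact_frequency(
    trajs: Sequence[DimerTrajectory] | DimerTrajectory,
    ligand_name: str,
    cutoff: float = DEFAULT_CUTOFF,
) -> ContactFrequencyTable:
    """Frequency of each protein residue contacting the named ligand's heavy
    atoms (e.g. the GTP bound to alpha-tubulin)."""
    if isinstance(trajs, DimerTrajectory):
        trajs = [trajs]
    trajs = list(trajs)
    top = _check_shared_topology(trajs)
    lig = top.ligand_atoms(ligand_name, heavy_only=True)
    protein = np.flatnonzero(~top.is_ligand & top.heavy_mask)
    run_ids = [t.run_id for t in trajs]
    frames_per_run = dict.fromkeys(run_ids, 0)
    res_hits: dict[ResKey, dict[str, int]] = {}
    for traj in trajs:
        for frame in traj.coords:
            frames_per_run[traj.run_id] += 1
            pairs = frame_contacts(frame, top, protein, lig, cutoff)
            for key_protein, _ in pairs:
                res_hits.setdefault(key_protein, dict.fromkeys(run_ids, 0))[
                    traj.run_id
                ] += 1
    info = _role_and_name(top)
    rows = []
    for row in _frequency_rows(res_hits, run_ids, frames_per_run):
        key = row.pop("_key")
        role, resname = info[key]
        rows.append({"role": role, "resid": key[1], "resname": resname, **row})
    cols = ["role", "resid", "resname", "frequency"] + [f"freq_{r}" for r in run_ids]
    return ContactFrequencyTable(
        per_residue=pd.DataFrame(rows, columns=cols),
        per_pair=pd.DataFrame(
            columns=["resid_a", "resname_a", "resid_b", "resname_b", "frequency"]
        ),
        n_frames=sum(frames_per_run.values()),
        cutoff=cutoff,
    )
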
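"""Readers, writers and the shared data model.

Conventions used throughout the package:

* residue numbering is 1-based, matching the crystallographic and mutagenesis
  literature on tubulin (Gln245, Val353, ...);
* angles are stored and reported in degrees;
* coordinates are in Angstroms;
* each chain of a dimer carries a *role*, ``"TUBA"`` (alpha-tubulin) or
  ``"TUBB"`` (beta-tubulin).  PDB chain labels are dialect-dependent, so the
  role assignment comes from the caller (default: first chain is TUBA);
* a *heavy atom* is any atom whose element is not hydrogen.  Hydrogens are
  silently excluded from contact analysis even when present.
"""

from __future__ import annotations

import io as _stdio
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "AngularTrack",
    "DimerTrajectory",
    "MissingAtomError",
    "ResidueSelection",
    "Topology",
    "default_selection",
    "load_reference_sequences",
    "load_selection",
    "percent_identity",
    "read_angular_tracks",
    "read_fasta",
    "read_trajectory",
    "write_angular_tracks",
    "write_trajectory",
]

#: residue names recognised as ligands rather than protein
LIGAND_RESNAMES = frozenset({"GTP", "GDP", "MG", "CA", "HOH", "WAT", "SOL"})

_AA1 = "ACDEFGHIKLMNPQRSTVWY"


class MissingAtomError(KeyError):
    """An atom requested by (role, residue, name) is absent from the topology."""


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------


@dataclass
class Topology:
    """Atom-level description of a two-chain dimer with optional ligands.

    Arrays are parallel, one entry per atom.  ``roles`` maps a chain identifier
    to ``"TUBA"`` or ``"TUBB"``; ligand residues belong to the chain whose
    identifier they carry but are excluded from protein selections.
    """

    ids: np.ndarray          # unique atom serials
    names: np.ndarray        # atom names, e.g. "CA", "CD"
    elements: np.ndarray     # element symbols, upper-case
    resids: np.ndarray       # 1-based residue numbers
    resnames: np.ndarray
    chain_ids: np.ndarray
    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(np.unique(self.ids)) != len(self.ids):
            raise ValueError("atom ids must be unique")
        arrays = (self.names, self.elements, self.resids, self.resnames, self.chain_ids)
        if any(len(a) != self.n_atoms for a in arrays):
            raise ValueError("topology arrays must have equal length")

    @property
    def n_atoms(self) -> int:
        return len(self.ids)

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.char.upper(self.elements.astype(str)) != "H"

    @property
    def is_ligand(self) -> np.ndarray:
        return np.isin(self.resnames, sorted(LIGAND_RESNAMES))

    def role_of(self, role: str) -> np.ndarray:
        """Boolean mask of protein atoms belonging to the chain with ``role``."""
        chains = [c for c, r in self.roles.items() if r == role]
        if not chains:
            raise ValueError(f"no chain assigned role {role!r}; roles: {self.roles}")
        return np.isin(self.chain_ids, chains) & ~self.is_ligand

    def select(
        self,
        role: str,
        resid_range: tuple[int, int] | None = None,
        atom_names: Sequence[str] | None = None,
        heavy_only: bool = False,
    ) -> np.ndarray:
        """Indices of atoms in a chain role, optionally restricted by residue
        range (inclusive, 1-based) and atom names."""
        mask = self.role_of(role)
        if resid_range is not None:
            lo, hi = resid_range
            mask &= (self.resids >= lo) & (self.resids <= hi)
        if atom_names is not None:
            mask &= np.isin(self.names, list(atom_names))
        if heavy_only:
            mask &= self.heavy_mask
        return np.flatnonzero(mask)

    def atom_index(self, role: str, resid: int, name: str) -> int:
        """Index of a single atom addressed as (chain role, residue, atom name)."""
        mask = self.role_of(role) & (self.resids == resid) & (self.names == name)
        idx = np.flatnonzero(mask)
        if len(idx) == 0:
            raise MissingAtomError(
                f"atom {name!r} of residue {resid} in chain role {role!r} "
                "is not present in the topology"
            )
        return int(idx[0])

    def ligand_atoms(self, ligand_name: str, heavy_only: bool = True) -> np.ndarray:
        mask = self.resnames == ligand_name
        if not mask.any():
            raise ValueError(f"ligand {ligand_name!r} absent from topology")
        if heavy_only:
            mask &= self.heavy_mask
        return np.flatnonzero(mask)


@dataclass
class DimerTrajectory:
    """A topology plus ordered coordinate frames at a fixed time stride.

    ``coords`` has shape ``(n_frames, n_atoms, 3)`` in Angstroms and
    ``frame_interval`` is the time per frame in the caller's unit (100 ps for
    the MD inputs this package emulates).
    """

    topology: Topology
    coords: np.ndarray
    frame_interval: float
    run_id: str = "run"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"coordinate frames have {self.coords.shape[1]} atoms but the "
                f"topology has {self.topology.n_atoms}"
            )
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def __len__(self) -> int:
        return self.n_frames


@dataclass
class AngularTrack:
    """One labelled spot or molecule: tilting and twisting angle series.

    Angles are in degrees and assumed continuous (unwrapped).  ``frame_interval``
    is the time per frame (50 ms for the DXT measurements this package
    emulates); it is metadata declared with the data, never inferred.
    """

    track_id: str
    theta: np.ndarray
    chi: np.ndarray
    frame_interval: float

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.chi = np.asarray(self.chi, dtype=float)
        if self.theta.ndim != 1 or self.chi.ndim != 1:
            raise ValueError("angle series must be one-dimensional")
        if len(self.theta) != len(self.chi):
            raise ValueError("theta and chi must have the same length")
        if len(self.theta) < 2:
            raise ValueError("a track needs at least two frames")
        if not (np.isfinite(self.theta).all() and np.isfinite(self.chi).all()):
            raise ValueError("angle series contain non-finite values")

    def __len__(self) -> int:
        return len(self.theta)

    def component(self, name: str) -> np.ndarray:
        if name not in ("theta", "chi"):
            raise ValueError(f"unknown component {name!r}")
        return getattr(self, name)


@dataclass
class ResidueSelection:
    """Named residue ranges and reference atoms used by the analysis stages.

    ``core`` maps a chain role to an inclusive 1-based residue range; the
    defaults are the structured tubulin bodies without the acidic C-terminal
    tail.  ``reference_atoms`` names the atoms of the two-state loop analysis
    as ``(role, resid, atom_name)`` triples.
    """

    core: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {"TUBA": (1, 436), "TUBB": (1, 427)}
    )
    interface: dict[str, tuple[int, int]] | None = None
    loop: tuple[int, int] = (243, 249)  # T7 loop of beta-tubulin
    reference_atoms: dict[str, tuple[str, int, str]] = field(
        default_factory=lambda: {
            "loop_probe": ("TUBB", 245, "CD"),       # Gln245 side chain
            "interface_anchor": ("TUBA", 11, "CD"),  # Gln11 side chain
            "internal_anchor": ("TUBB", 353, "CA"),  # Val353
        }
    )

    def validate(self, topology: Topology) -> None:
        for role, (lo, hi) in self.core.items():
            resids = topology.resids[topology.role_of(role)]
            if lo < resids.min() or hi > resids.max():
                raise ValueError(
                    f"core range {lo}-{hi} for {role} outside topology residues "
                    f"{resids.min()}-{resids.max()}"
                )

    def interface_range(self, role: str) -> tuple[int, int] | None:
        if self.interface is None:
            return None
        return self.interface.get(role)


# ---------------------------------------------------------------------------
# trajectory I/O (MDAnalysis behind the scenes)
# ---------------------------------------------------------------------------


def _mda():
    import MDAnalysis as mda

    return mda


def _topology_from_universe(u, chain_roles: Mapping[str, str] | None) -> Topology:
    atoms = u.atoms
    try:
        chain_ids = atoms.chainIDs.astype(str)
    except AttributeError:
        chain_ids = atoms.segids.astype(str)
    try:
        elements = atoms.elements.astype(str)
    except AttributeError:
        from MDAnalysis.topology.guessers import guess_types

        elements = guess_types(atoms.names).astype(str)
    roles = dict(chain_roles) if chain_roles else {}
    if not roles:
        seen: list[str] = []
        lig = np.isin(atoms.resnames, sorted(LIGAND_RESNAMES))
        for cid, is_lig in zip(chain_ids, lig):
            if not is_lig and cid not in seen:
                seen.append(cid)
        default_roles = ["TUBA", "TUBB"]
        for cid, role in zip(seen, default_roles):
            roles[cid] = role
    return Topology(
        ids=atoms.ids.copy(),
        names=atoms.names.astype(str),
        elements=np.char.upper(elements),
        resids=atoms.resids.copy(),
        resnames=atoms.resnames.astype(str),
        chain_ids=chain_ids,
        roles=roles,
    )


def read_trajectory(
    topology_path: str | Path,
    frames_path: str | Path | None,
    frame_interval: float,
    run_id: str = "run",
    chain_roles: Mapping[str, str] | None = None,
) -> DimerTrajectory:
    """Read a topology (PDB) plus coordinate frames (multi-model PDB, DCD or
    XTC) into a :class:`DimerTrajectory`.

    ``chain_roles`` maps chain identifiers to ``"TUBA"``/``"TUBB"``; by default
    the first protein chain encountered is TUBA and the second TUBB.
    """
    mda = _mda()
    if not frame_interval > 0:
        raise ValueError("frame_interval must be positive")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            if frames_path is None:
                u = mda.Universe(str(topology_path))
            else:
                u = mda.Universe(str(topology_path), str(frames_path))
        except ValueError as exc:  # MDAnalysis reports atom-count mismatches here
            raise ValueError(
                f"atom count mismatch between {topology_path} and {frames_path}: {exc}"
            ) from exc
        topology = _topology_from_universe(u, chain_roles)
        frames = [ts.positions.astype(float).copy() for ts in u.trajectory]
    if frames and frames[0].shape[0] != topology.n_atoms:
        raise ValueError("atom count mismatch between topology and frames")
    return DimerTrajectory(
        topology=topology,
        coords=np.stack(frames),
        frame_interval=frame_interval,
        run_id=run_id,
    )


def _universe_from(traj: DimerTrajectory):
    mda = _mda()
    top = traj.topology
    n_res_keys = list(dict.fromkeys(zip(top.chain_ids, top.resids)))
    res_of_atom = np.array(
        [n_res_keys.index((c, r)) for c, r in zip(top.chain_ids, top.resids)]
    )
    seg_keys = list(dict.fromkeys(top.chain_ids))
    seg_of_res = np.array([seg_keys.index(c) for c, _ in n_res_keys])
    u = mda.Universe.empty(
        n_atoms=top.n_atoms,
        n_residues=len(n_res_keys),
        n_segments=len(seg_keys),
        atom_resindex=res_of_atom,
        residue_segindex=seg_of_res,
        trajectory=True,
    )
    u.add_TopologyAttr("names", top.names)
    u.add_TopologyAttr("elements", top.elements)
    u.add_TopologyAttr("resids", np.array([r for _, r in n_res_keys]))
    u.add_TopologyAttr("resnames", [top.resnames[res_of_atom == i][0] for i in range(len(n_res_keys))])
    u.add_TopologyAttr("segids", seg_keys)
    u.add_TopologyAttr("chainIDs", top.chain_ids)
    u.add_TopologyAttr("ids", top.ids)
    u.atoms.positions = traj.coords[0]
    return u


def write_trajectory(
    traj: DimerTrajectory,
    topology_path: str | Path,
    frames_path: str | Path | None = None,
) -> None:
    """Write frame 0 as a PDB topology and, optionally, all frames to a
    multi-model PDB, DCD or XTC file chosen by extension."""
    mda = _mda()
    u = _universe_from(traj)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(topology_path))
        if frames_path is not None:
            with mda.Writer(str(frames_path), n_atoms=traj.topology.n_atoms) as w:
                for frame in traj.coords:
                    u.atoms.positions = frame
                    w.write(u.atoms)


# ---------------------------------------------------------------------------
# angular-track CSV dialect
# ---------------------------------------------------------------------------


def write_angular_tracks(tracks: Sequence[AngularTrack], path: str | Path) -> None:
    """Write tracks to the package's CSV dialect.

    The file starts with ``# key=value`` metadata lines (``frame_interval``,
    ``angle_unit``) followed by a header ``track_id,frame,theta_deg,chi_deg``.
    Angles are written with 9 significant digits, which round-trips the
    double-precision values produced by the generators at the declared
    precision.
    """
    tracks = list(tracks)
    if not tracks:
        raise ValueError("no tracks to write")
    intervals = {t.frame_interval for t in tracks}
    if len(intervals) != 1:
        raise ValueError("all tracks in one file must share a frame_interval")
    with open(path, "w") as fh:
        fh.write(f"# frame_interval={tracks[0].frame_interval!r}\n")
        fh.write("# angle_unit=degrees\n")
        fh.write("track_id,frame,theta_deg,chi_deg\n")
        for t in tracks:
            for i, (th, ch) in enumerate(zip(t.theta, t.chi)):
                fh.write(f"{t.track_id},{i},{th:.9g},{ch:.9g}\n")


def read_angular_tracks(path: str | Path) -> list[AngularTrack]:
    """Read angular tracks from CSV; one :class:`AngularTrack` per track_id.

    Rows may arrive in any order; frames are sorted ascending per track.  A gap
    in the frame numbering of a track is an error: tracks carry no missing
    samples.
    """
    meta: dict[str, str] = {}
    with open(path) as fh:
        text = fh.read()
    for line in text.splitlines():
        if line.startswith("#") and "=" in line:
            key, _, value = line.lstrip("# ").partition("=")
            meta[key.strip()] = value.strip()
    if "frame_interval" not in meta:
        raise ValueError(f"{path}: missing '# frame_interval=' metadata line")
    frame_interval = float(meta["frame_interval"])
    df = pd.read_csv(_stdio.StringIO(text), comment="#")
    required = {"track_id", "frame", "theta_deg", "chi_deg"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    for col in ("theta_deg", "chi_deg"):
        if not np.issubdtype(df[col].dtype, np.number):
            raise ValueError(f"{path}: non-numeric values in column {col}")
    tracks = []
    for track_id, g in df.groupby("track_id", sort=True):
        g = g.sort_values("frame")
        frames = g["frame"].to_numpy()
        expected = np.arange(frames[0], frames[0] + len(frames))
        if not np.array_equal(frames, expected):
            missing = sorted(set(expected) - set(frames))
            raise ValueError(
                f"{path}: track {track_id!r} has missing frames {missing[:5]}"
            )
        tracks.append(
            AngularTrack(
                track_id=str(track_id),
                theta=g["theta_deg"].to_numpy(),
                chi=g["chi_deg"].to_numpy(),
                frame_interval=frame_interval,
            )
        )
    return tracks


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {identifier: sequence} mapping."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def load_reference_sequences() -> dict[str, str]:
    """Bundled human tubulin isoform sequences (TUBA1A, TUBA1B, TUBB3, TUBB5).

    These are offline copies of the canonical sequences keyed by gene symbol;
    the FASTA header records the corresponding UniProt accessions and the
    caveats of the bundled copies.  Verify against UniProt where network access
    is available.
    """
    ref = resources.files("tubudyn").joinpath("data/tubulin_isoforms.fasta")
    with resources.as_file(ref) as path:
        return read_fasta(path)


def percent_identity(
    seq_a: str,
    seq_b: str,
    include_terminal_gaps: bool = False,
) -> float:
    """Percent identity of two amino-acid sequences under global alignment.

    The alignment uses match +1, mismatch 0 and a simple linear gap penalty of
    -1.  Identity is the number of identical aligned positions divided by the
    number of aligned columns and reported to two decimals.  By default
    terminal-gap columns (the overhang of the longer sequence) are excluded
    from the denominator, which is the convention consistent with published
    tubulin isoform identities; pass ``include_terminal_gaps=True`` for the
    full-alignment-length convention.
    """
    from Bio import Align

    for label, seq in (("seq_a", seq_a), ("seq_b", seq_b)):
        if not seq:
            raise ValueError(f"{label} is empty")
        bad = set(seq.upper()) - set(_AA1)
        if bad:
            raise ValueError(f"{label} contains non-amino-acid characters: {sorted(bad)}")
    a, b = seq_a.upper(), seq_b.upper()
    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=1.0,
        mismatch_score=0.0,
        open_gap_score=-1.0,
        extend_gap_score=-1.0,
    )
    alignment = aligner.align(a, b)[0]
    col_a, col_b = (str(s) for s in alignment)
    n_cols = len(col_a)
    start, stop = 0, n_cols
    if not include_terminal_gaps:
        while start < n_cols and (col_a[start] == "-" or col_b[start] == "-"):
            start += 1
        while stop > start and (col_a[stop - 1] == "-" or col_b[stop - 1] == "-"):
            stop -= 1
    matches = sum(
        1 for x, y in zip(col_a[start:stop], col_b[start:stop]) if x == y and x != "-"
    )
    denom = stop - start
    if denom == 0:
        raise ValueError("alignment has no aligned columns")
    return round(100.0 * matches / denom, 2)


# ---------------------------------------------------------------------------
# selection / config files
# ---------------------------------------------------------------------------


def load_selection(path: str | Path) -> ResidueSelection:
    """Read a residue-selection config (YAML) into a :class:`ResidueSelection`."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = {}
    if "core" in raw:
        kwargs["core"] = {role: tuple(rng) for role, rng in raw["core"].items()}
    if "interface" in raw and raw["interface"] is not None:
        kwargs["interface"] = {role: tuple(rng) for role, rng in raw["interface"].items()}
    if "loop" in raw:
        kwargs["loop"] = tuple(raw["loop"])
    if "reference_atoms" in raw:
        kwargs["reference_atoms"] = {
            key: (spec[0], int(spec[1]), spec[2]) for key, spec in raw["reference_atoms"].items()
        }
    return ResidueSelection(**kwargs)


def default_selection() -> ResidueSelection:
    """The default tubulin selection: cores TUBA 1-436 / TUBB 1-427, T7 loop
    243-249, and the Gln245/Gln11/Val353 reference atoms."""
    return ResidueSelection()
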
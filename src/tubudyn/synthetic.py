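"""Ground-truth generators for angular tracks and two-domain dimer
trajectories.

These stand in for the DXT detector and the MD engine so that every analysis
stage can be verified by parameter recovery: the generators take the quantity
the analysis is supposed to measure (diffusion constants, twist/tilt variance,
contact geometry, loop-state occupancies) as an *input* and the tests check
that the pipeline returns it.

Design choices that make the recovery exact rather than approximate:

* the loop flip is a two-state (telegraph) Markov chain, so occupancies and
  switching rates are exact ground truth, not emergent properties of a
  potential;
* domain point clouds are deterministic Fibonacci-sphere packings, so geometry
  tests are reproducible without stored fixtures;
* all randomness flows through one ``numpy`` PCG64 generator seeded from the
  recorded ``seed``, so outputs are bit-reproducible across platforms;
* generated angle series are continuous (unwrapped) by construction.

This is a statistical stand-in, not an MD engine: no force field, solvent or
thermostat is emulated.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from typing import Literal

import numpy as np
from scipy.spatial.transform import Rotation

from tubudyn.io import AngularTrack, DimerTrajectory, Topology

__all__ = [
    "DimerParams",
    "RotorParams",
    "fibonacci_sphere",
    "make_paired_scenario",
    "simulate_dimer",
    "simulate_rotor",
    "simulate_telegraph",
    "simulate_two_mode_dimer",
]


# ---------------------------------------------------------------------------
# Brownian rotor (DXT stand-in)
# ---------------------------------------------------------------------------


@dataclass
class RotorParams:
    """Parameters of the Brownian angular-track generator.

    ``d_theta``/``d_chi`` are rotational diffusion constants in
    degrees^2 per time unit; ``frame_interval`` is the time per frame in the
    same unit (the DXT measurements this emulates use 50 ms frames).  Optional
    ``drift`` (degrees/time) adds directed rotation and ``noise_sd`` (degrees)
    adds i.i.d. measurement noise on every sample.
    """

    d_theta: float = 0.08
    d_chi: float = 0.2
    frame_interval: float = 0.05
    n_frames: int = 300
    n_tracks: int = 150
    seed: int = 0
    drift: tuple[float, float] = (0.0, 0.0)
    noise_sd: float = 0.0

    def validate(self) -> None:
        if self.d_theta < 0 or self.d_chi < 0:
            raise ValueError("diffusion constants must be non-negative")
        if self.n_frames < 2:
            raise ValueError("n_frames must be at least 2")
        if self.n_tracks < 1:
            raise ValueError("n_tracks must be at least 1")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    def manifest(self) -> dict:
        out = {"generator": "rotor", **asdict(self)}
        out["drift"] = list(self.drift)  # JSON round-trip cleanly
        return out


def _random_walks(
    rng: np.random.Generator, n_tracks: int, n_frames: int, step_var: float, drift_step: float
) -> np.ndarray:
    steps = rng.normal(0.0, np.sqrt(step_var), size=(n_tracks, n_frames - 1)) + drift_step
    walks = np.concatenate(
        [np.zeros((n_tracks, 1)), np.cumsum(steps, axis=1)], axis=1
    )
    return walks


def simulate_rotor(params: RotorParams) -> list[AngularTrack]:
    """Generate Brownian angular tracks.

    Each component evolves as an independent Gaussian random walk,
    ``alpha(t + dt) = alpha(t) + N(0, 2 D dt) + drift * dt``, started at 0,
    with optional i.i.d. measurement noise added afterwards.  Output is
    bit-identical for a given seed.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    dt = params.frame_interval
    theta = _random_walks(
        rng, params.n_tracks, params.n_frames, 2.0 * params.d_theta * dt, params.drift[0] * dt
    )
    chi = _random_walks(
        rng, params.n_tracks, params.n_frames, 2.0 * params.d_chi * dt, params.drift[1] * dt
    )
    if params.noise_sd > 0:
        theta = theta + rng.normal(0.0, params.noise_sd, theta.shape)
        chi = chi + rng.normal(0.0, params.noise_sd, chi.shape)
    return [
        AngularTrack(
            track_id=f"spot{i:04d}",
            theta=theta[i],
            chi=chi[i],
            frame_interval=dt,
        )
        for i in range(params.n_tracks)
    ]


def make_paired_scenario(
    low_d_params: RotorParams, high_d_params: RotorParams
) -> tuple[dict[str, list[AngularTrack]], dict]:
    """Two labelled rotor ensembles mirroring the neuronal-vs-ubiquitous
    comparison: a "neuronal-like" ensemble with the lower twisting diffusion
    constant and a "ubiquitous-like" one with the higher.

    Returns ``(ensembles, manifest)`` where the manifest records the ground
    truth, including the programmed D ratios, and round-trips through JSON.
    """
    for p in (low_d_params, high_d_params):
        p.validate()
    if low_d_params.seed == high_d_params.seed:
        high_d_params = replace(high_d_params, seed=high_d_params.seed + 1)
    ensembles = {
        "neuronal_like": simulate_rotor(low_d_params),
        "ubiquitous_like": simulate_rotor(high_d_params),
    }
    manifest = {
        "generator": "paired_rotor",
        "neuronal_like": low_d_params.manifest(),
        "ubiquitous_like": high_d_params.manifest(),
        "d_chi_ratio": (
            low_d_params.d_chi / high_d_params.d_chi if high_d_params.d_chi else None
        ),
        "d_theta_ratio": (
            low_d_params.d_theta / high_d_params.d_theta if high_d_params.d_theta else None
        ),
    }
    return ensembles, manifest


# ---------------------------------------------------------------------------
# telegraph process
# ---------------------------------------------------------------------------


def simulate_telegraph(
    rng: np.random.Generator,
    n_frames: int,
    occupancy_a: float,
    switch_rate: float,
) -> np.ndarray:
    """Two-state Markov chain with stationary occupancy ``occupancy_a``.

    Per-frame transition probabilities are ``p(A->B) = switch_rate * (1 - occ)``
    and ``p(B->A) = switch_rate * occ`` so the stationary distribution is
    exactly ``occ`` and the correlation time is ``1 / switch_rate`` frames.
    The initial state is drawn from the stationary distribution.  Returns a
    boolean array, True for state A.
    """
    if not 0.0 <= occupancy_a <= 1.0:
        raise ValueError("occupancy must be in [0, 1]")
    p_ab = switch_rate * (1.0 - occupancy_a)
    p_ba = switch_rate * occupancy_a
    if p_ab > 1.0 or p_ba > 1.0:
        raise ValueError("switch_rate too large for a per-frame Markov chain")
    u = rng.random(n_frames)
    states = np.empty(n_frames, dtype=bool)
    states[0] = u[0] < occupancy_a
    for t in range(1, n_frames):
        if states[t - 1]:
            states[t] = u[t] >= p_ab
        else:
            states[t] = u[t] < p_ba
    return states


# ---------------------------------------------------------------------------
# two-domain dimer builder
# ---------------------------------------------------------------------------


def fibonacci_sphere(n: int, radius: float = 1.0) -> np.ndarray:
    """Deterministic, nearly uniform packing of ``n`` points on a sphere."""
    if n < 1:
        raise ValueError("need at least one point")
    k = np.arange(n)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    phi = 2.0 * np.pi * k / golden
    return radius * np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


@dataclass
class DimerParams:
    """Parameters of the synthetic two-domain dimer generator.

    The TUBA-role domain sits at the origin and stays fixed (apart from
    thermal jitter); the TUBB-role domain, centred ``separation`` Angstroms up
    the z axis, moves rigidly with a programmed twist (about the dimer axis)
    and tilt (two-component swing) process.  The angular process is
    Ornstein-Uhlenbeck: free rotational diffusion with constant
    ``stationary_sd^2 / relaxation_frames`` (deg^2/frame) at short times,
    confined at long times as a substrate-anchored molecule is.  Set
    ``relaxation_frames=inf`` (``process="diffusion"``) for a free random
    walk.

    Interface contacts are ``n_interface_pairs`` opposed atom pairs at
    ``contact_rest_distance`` (plus jitter); the T7-style loop toggles between
    a TUBA-facing and a TUBB-facing conformation via a telegraph process with
    stationary occupancy ``loop_occupancy_a``.  Residue numbering follows the
    tubulin convention so the Gln245/Gln11/Val353 reference atoms resolve.
    """

    n_residues_a: int = 436
    n_residues_b: int = 427
    radius: float = 22.0
    separation: float = 46.0
    twist_sd: float = 5.0          # deg, stationary
    tilt_sd: float = 2.5           # deg per swing component, stationary
    relaxation_frames: float = 500.0
    process: Literal["ou", "diffusion"] = "ou"
    n_interface_pairs: int = 10
    contact_rest_distance: float = 3.4
    jitter_sd: float = 0.08
    loop_occupancy_a: float = 0.7
    loop_switch_rate: float = 0.1
    include_gtp: bool = True
    frame_interval: float = 100.0  # ps per frame, MD-like stride
    n_frames: int = 2000
    seed: int = 0
    run_id: str = "run1"

    def validate(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be at least 2")
        if self.contact_rest_distance <= 0:
            raise ValueError("geometrically impossible: contact rest distance <= 0")
        if self.separation <= 0 or self.radius <= 0:
            raise ValueError("separation and radius must be positive")
        if not 0.0 <= self.loop_occupancy_a <= 1.0:
            raise ValueError("loop occupancy must be in [0, 1]")
        if self.twist_sd < 0 or self.tilt_sd < 0:
            raise ValueError("angle scales must be non-negative")
        if self.n_residues_b < 360 or self.n_residues_a < 230:
            raise ValueError(
                "domains too small for the tubulin residue conventions "
                "(need TUBA >= 230, TUBB >= 360 residues)"
            )

    @property
    def twist_diffusion_per_frame(self) -> float:
        """Short-time twist diffusion constant in deg^2/frame."""
        return self.twist_sd**2 / self.relaxation_frames

    @property
    def twist_diffusion(self) -> float:
        """Short-time twist diffusion constant in deg^2 per time unit."""
        return self.twist_diffusion_per_frame / self.frame_interval

    def manifest(self) -> dict:
        return {
            "generator": "dimer",
            **asdict(self),
            "twist_diffusion_per_frame": self.twist_diffusion_per_frame,
            "twist_diffusion": self.twist_diffusion,
        }


# fixed residue conventions of the synthetic dimer (tubulin numbering)
_Q11, _Y224, _T73 = 11, 224, 73          # TUBA anchors
_Q245, _V353 = 245, 353                  # TUBB loop probe and internal anchor
_LOOP_RESIDUES = (243, 244, 245, 246, 247, 248, 249)
_IFACE_A_START, _IFACE_B_START = 201, 301


def _ou_series(
    rng: np.random.Generator,
    n: int,
    stationary_sd: float,
    relaxation: float,
    free: bool,
) -> np.ndarray:
    """Ornstein-Uhlenbeck (or free random-walk) angle series started at 0.

    The short-time step variance is ``2 * (sd^2 / relaxation)`` per frame in
    both modes, so the programmed short-time diffusion constant is identical.
    """
    if stationary_sd == 0:
        return np.zeros(n)
    step_var = 2.0 * stationary_sd**2 / relaxation
    steps = rng.normal(0.0, np.sqrt(step_var), size=n - 1)
    out = np.empty(n)
    out[0] = 0.0
    if free:
        out[1:] = np.cumsum(steps)
        return out
    decay = 1.0 - 1.0 / relaxation
    for t in range(1, n):
        out[t] = out[t - 1] * decay + steps[t - 1]
    return out


def _build_reference(params: DimerParams):
    """Reference geometry plus the topology arrays.

    Returns (topology, coords_a, coords_b_states) where coords_b_states is a
    pair of B-domain reference configurations (loop state A / state B); all
    non-loop B atoms are identical in both.
    """
    k = params.n_interface_pairs
    if k > 60:
        raise ValueError("too many interface pairs for the domain surface")
    iface_z = params.radius - 1.5  # just under the A-domain apex
    rest = params.contact_rest_distance

    names: list[str] = []
    elements: list[str] = []
    resids: list[int] = []
    resnames: list[str] = []
    chains: list[str] = []
    pos_a: list[np.ndarray] = []

    # --- domain A (TUBA role, chain A), one CA per residue ----------------
    sphere_a = fibonacci_sphere(params.n_residues_a, params.radius)
    special_a = {_Q11: "GLN", _Y224: "TYR", _T73: "THR"}
    angles = np.linspace(0.0, 2.0 * np.pi, k, endpoint=False)
    iface_a = np.column_stack(
        [8.0 * np.cos(angles), 8.0 * np.sin(angles), np.full(k, iface_z)]
    )
    # the loop/anchor assembly sits close to the dimer (z) axis, as the T7
    # loop does at the intra-dimer interface; near the axis the twist motion
    # barely moves it, so programmed contact distances stay in force
    q11_ca = np.array([2.0, 0.0, params.radius - 2.4])
    q11_cd = np.array([2.0, 0.0, params.radius - 1.0])
    for r in range(1, params.n_residues_a + 1):
        resname = special_a.get(r, "GLY")
        if _IFACE_A_START <= r < _IFACE_A_START + k:
            p = iface_a[r - _IFACE_A_START]
        elif r == _Q11:
            p = q11_ca
        else:
            p = sphere_a[r - 1]
        names.append("CA")
        elements.append("C")
        resids.append(r)
        resnames.append(resname)
        chains.append("A")
        pos_a.append(p)
    # Gln11 side-chain probe
    names.append("CD")
    elements.append("C")
    resids.append(_Q11)
    resnames.append("GLN")
    chains.append("A")
    pos_a.append(q11_cd)

    # --- domain B (TUBB role, chain B) ------------------------------------
    center_b = np.array([0.0, 0.0, params.separation])
    sphere_b = fibonacci_sphere(params.n_residues_b, params.radius) + center_b
    iface_b = iface_a + np.array([0.0, 0.0, rest])
    special_b = {_Q245: "GLN", 246: "LEU", 247: "ASN", _V353: "VAL"}
    v353 = np.array([2.0, 0.0, iface_z + 14.0])
    cd_state_a = np.array([2.0, 0.0, iface_z + rest])           # near Gln11
    cd_state_b = v353 - np.array([0.0, 0.0, rest])              # near Val353
    loop_offsets = {
        243: np.array([-2.5, 0.8, 1.2]),
        244: np.array([-1.2, -0.6, 0.6]),
        245: np.array([1.4, 0.0, 0.3]),  # CA relative to the Cdelta probe
        246: np.array([2.6, 0.7, 1.0]),
        247: np.array([3.6, -0.5, 1.8]),
        248: np.array([4.4, 0.6, 2.8]),
        249: np.array([5.0, -0.4, 3.9]),
    }
    pos_b_a: list[np.ndarray] = []  # loop in state A
    pos_b_b: list[np.ndarray] = []  # loop in state B
    for r in range(1, params.n_residues_b + 1):
        resname = special_b.get(r, "GLY")
        if _IFACE_B_START <= r < _IFACE_B_START + k:
            pa = pb = iface_b[r - _IFACE_B_START]
        elif r in loop_offsets:
            pa = cd_state_a + loop_offsets[r]
            pb = cd_state_b + loop_offsets[r]
        elif r == _V353:
            pa = pb = v353
        else:
            pa = pb = sphere_b[r - 1]
        names.append("CA")
        elements.append("C")
        resids.append(r)
        resnames.append(resname)
        chains.append("B")
        pos_b_a.append(pa)
        pos_b_b.append(pb)
    # Gln245 side-chain probe
    names.append("CD")
    elements.append("C")
    resids.append(_Q245)
    resnames.append("GLN")
    chains.append("B")
    pos_b_a.append(cd_state_a)
    pos_b_b.append(cd_state_b)

    # --- optional GTP ligand next to Gln11 --------------------------------
    if params.include_gtp:
        gtp_center = q11_cd + np.array([0.0, 2.6, 0.0])
        for i, off in enumerate(
            (np.zeros(3), np.array([1.2, 0.4, 0.0]), np.array([-1.0, 0.6, 0.8]))
        ):
            names.append(("PG", "O1G", "N9")[i])
            elements.append(("P", "O", "N")[i])
            resids.append(500)
            resnames.append("GTP")
            chains.append("A")
            pos_a.append(gtp_center + off)

    n_atoms = len(names)
    topology = Topology(
        ids=np.arange(1, n_atoms + 1),
        names=np.array(names),
        elements=np.array(elements),
        resids=np.array(resids),
        resnames=np.array(resnames),
        chain_ids=np.array(chains),
        roles={"A": "TUBA", "B": "TUBB"},
    )
    return topology, np.asarray(pos_a), (np.asarray(pos_b_a), np.asarray(pos_b_b))


def simulate_dimer(params: DimerParams) -> tuple[DimerTrajectory, dict]:
    """Generate a two-domain dimer trajectory with programmed relative motion.

    Domain A stays fixed (plus jitter); domain B is rigidly rotated each frame
    by the programmed twist/tilt process about the inter-centroid (z) axis,
    pivoting at the interface; the loop toggles between its two conformations
    via a telegraph process.  Returns ``(trajectory, manifest)`` where the
    manifest records every ground-truth parameter plus the realised per-frame
    twist/tilt angles and loop states.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    topology, ref_a, (ref_b_state_a, ref_b_state_b) = _build_reference(params)
    n = params.n_frames
    free = params.process == "diffusion"
    twist = _ou_series(rng, n, params.twist_sd, params.relaxation_frames, free)
    swing_x = _ou_series(rng, n, params.tilt_sd, params.relaxation_frames, free)
    swing_y = _ou_series(rng, n, params.tilt_sd, params.relaxation_frames, free)
    loop_a = simulate_telegraph(rng, n, params.loop_occupancy_a, params.loop_switch_rate)

    is_b = topology.chain_ids == "B"
    pivot = np.array([0.0, 0.0, params.radius + 1.0])
    n_atoms = topology.n_atoms
    coords = np.empty((n, n_atoms, 3))
    tilt = np.hypot(swing_x, swing_y)
    for t in range(n):
        frame = np.empty((n_atoms, 3))
        frame[~is_b] = ref_a
        ref_b = ref_b_state_a if loop_a[t] else ref_b_state_b
        r_twist = Rotation.from_euler("z", twist[t], degrees=True)
        # swing: rotation moving the z axis by (swing_x, swing_y)
        ang = tilt[t]
        if ang > 0:
            axis = np.array([-swing_y[t], swing_x[t], 0.0]) / ang
            r_swing = Rotation.from_rotvec(np.radians(ang) * axis)
        else:
            r_swing = Rotation.identity()
        rot = r_swing * r_twist
        frame[is_b] = (ref_b - pivot) @ rot.as_matrix().T + pivot
        coords[t] = frame
    if params.jitter_sd > 0:
        coords += rng.normal(0.0, params.jitter_sd, coords.shape)

    traj = DimerTrajectory(
        topology=topology,
        coords=coords,
        frame_interval=params.frame_interval,
        run_id=params.run_id,
    )
    manifest = {
        **params.manifest(),
        "twist_true": twist.tolist(),
        "tilt_true": tilt.tolist(),
        "loop_state_a": loop_a.tolist(),
        "loop_occupancy_a_realised": float(loop_a.mean()),
    }
    return traj, manifest


def simulate_two_mode_dimer(
    n_frames: int = 3000,
    variance_ratio: float = 2.0,
    amplitude: float = 1.0,
    seed: int = 0,
    base_params: DimerParams | None = None,
) -> tuple[DimerTrajectory, dict]:
    """Dimer whose TUBB core oscillates along exactly two orthonormal rigid
    displacement patterns (a twist-like and a tilt-like mode) with programmed
    variance ratio — ground truth for the PCA stage.

    Frame ``t`` displaces the B domain by ``a1(t) u1 + a2(t) u2`` where the
    amplitudes are i.i.d. Gaussian with variances ``variance_ratio : 1``
    (times ``amplitude^2``).  Returns the trajectory plus a manifest carrying
    the exact mode patterns and programmed contribution ratios.
    """
    if variance_ratio <= 0:
        raise ValueError("variance_ratio must be positive")
    params = base_params or DimerParams(
        n_frames=n_frames, seed=seed, jitter_sd=0.0, include_gtp=False
    )
    topology, ref_a, (ref_b_state_a, _) = _build_reference(params)
    is_b = topology.chain_ids == "B"
    ref_b = ref_b_state_a
    # rigid twist pattern about z and tilt pattern about x, Gram-Schmidt
    # orthonormalised over the flattened 3N space
    pivot = np.array([0.0, 0.0, params.radius + 1.0])
    rel = ref_b - pivot
    z_hat = np.array([0.0, 0.0, 1.0])
    x_hat = np.array([1.0, 0.0, 0.0])
    u1 = np.cross(z_hat, rel).ravel()
    u1 /= np.linalg.norm(u1)
    u2 = np.cross(x_hat, rel).ravel()
    u2 -= (u2 @ u1) * u1
    u2 /= np.linalg.norm(u2)
    rng = np.random.default_rng(seed)
    a1 = rng.normal(0.0, amplitude * np.sqrt(variance_ratio), n_frames)
    a2 = rng.normal(0.0, amplitude, n_frames)
    disp = a1[:, None] * u1[None, :] + a2[:, None] * u2[None, :]
    coords = np.empty((n_frames, topology.n_atoms, 3))
    coords[:, ~is_b] = ref_a
    coords[:, is_b] = ref_b + disp.reshape(n_frames, -1, 3)
    traj = DimerTrajectory(
        topology=topology,
        coords=coords,
        frame_interval=params.frame_interval,
        run_id=f"two_mode_seed{seed}",
    )
    manifest = {
        "generator": "two_mode_dimer",
        "n_frames": n_frames,
        "variance_ratio": variance_ratio,
        "amplitude": amplitude,
        "seed": seed,
        "contribution_ratios_true": [
            variance_ratio / (variance_ratio + 1.0),
            1.0 / (variance_ratio + 1.0),
        ],
        "mode1": u1.tolist(),
        "mode2": u2.tolist(),
    }
    return traj, manifest
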
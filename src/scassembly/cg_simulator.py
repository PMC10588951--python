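"""Coarse-grained Brownian-dynamics simulator of SYCP1 head-to-head dissociation.

The model is a deliberately minimal stand-in for steered all-atom MD of the
alphaN-end "dimer of dimers": four 75-bead chains (one bead per residue of
the human 101-175 segment), arranged as two parallel-chain dimers joined
head-to-head through their 11-bead alphaN tips (h.101-111). Opposing axial
forces pull the two dimers apart while short-range attractive wells between
opposing tip beads hold the interface together; glutamate substitutions at
the interface are modelled purely as a multiplicative weakening of the well
depth (the ``GenotypeFactor`` scale), not as explicit electrostatics.

Dynamics are overdamped (position Langevin):

    dx = (F / gamma) dt + sqrt(2 kT dt / gamma) * xi

with no inertia, solvent, or pressure coupling. Reduced units: kT at 310 K
is 1 energy unit, lengths are Angstrom, times are ns. The per-atom steering
forces quoted in kJ mol^-1 nm^-1 are converted to per-bead forces using a
nominal 19 atoms per residue (see ``force_to_reduced``).

Genotype interface scales and the wild-type well depth are calibrated once
(so that wild-type assemblies survive the default run at the middle force
while the strongly destabilised mutants dissociate) and frozen in the
versioned ``data/cg_defaults.yaml``.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

from .core_model import AssemblyStructure, Trajectory

__all__ = [
    "CGModelParams",
    "SteeringConfig",
    "GenotypeFactor",
    "GENOTYPE_LABELS",
    "genotype_scale",
    "build_tetramer_model",
    "simulate",
    "simulate_free_diffusion",
    "force_to_reduced",
    "load_defaults",
    "STEERING_FORCES_KJ_MOL_NM",
]

# kT at 310 K in kJ/mol (R * T)
KT_310_KJ_PER_MOL = 8.31446e-3 * 310.0
# nominal atoms (incl. hydrogens) represented by one residue bead
ATOMS_PER_BEAD = 19
# the per-atom force settings of the steered assay, kJ mol^-1 nm^-1
STEERING_FORCES_KJ_MOL_NM = (0.025, 0.05, 0.075, 0.10)

N_TIP_BEADS = 11  # alphaN tip h.101-111, one bead per residue

_HUMAN_FIRST_RESIDUE = 101
_HUMAN_MARKER = 109


def load_defaults() -> dict:
    """Load the frozen, versioned calibration defaults."""
    with resources.files("scassembly.data").joinpath("cg_defaults.yaml").open() as fh:
        return yaml.safe_load(fh)


@dataclass(frozen=True)
class CGModelParams:
    """Geometry, interaction and integrator parameters (reduced units).

    Energies are kT(310 K); lengths Angstrom; times ns. ``friction`` is the
    per-bead drag gamma in kT*ns/A^2; ``temperature`` rescales kT relative
    to 310 K (0 is the noise-off limit used for closed-form checks).
    """

    beads_per_chain: int = 75
    bond_length: float = 1.5  # A, helical rise per residue
    bond_stiffness: float = 4.0  # kT/A^2
    bend_stiffness: float = 2.0  # kT/A^2 on 1-3 distances
    pairing_stiffness: float = 2.0  # kT/A^2 between paired chains of a dimer
    pairing_distance: float = 5.0  # A, lateral chain-chain spacing
    interface_well_depth: float | None = None  # kT per tip-bead pair; None -> frozen default
    interface_contact: float = 4.0  # A, well minimum r0
    interface_cutoff: float = 10.0  # A, attraction vanishes beyond this
    friction: float = 0.1  # kT*ns/A^2 per bead
    temperature: float = 310.0  # K; >= 0 (0 = deterministic limit)
    timestep: float = 0.004  # ns
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beads_per_chain < N_TIP_BEADS + 1:
            raise ValueError(
                f"beads_per_chain must be >= {N_TIP_BEADS + 1} to host the "
                f"{N_TIP_BEADS}-bead tip"
            )
        for name in (
            "bond_length",
            "bond_stiffness",
            "bend_stiffness",
            "pairing_stiffness",
            "friction",
            "timestep",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")
        if self.interface_well_depth is not None and self.interface_well_depth < 0:
            raise ValueError("interface_well_depth must be >= 0")
        if self.interface_cutoff <= self.interface_contact:
            raise ValueError("interface_cutoff must exceed interface_contact")

    @property
    def kT(self) -> float:
        return self.temperature / 310.0

    def resolved_well_depth(self) -> float:
        if self.interface_well_depth is not None:
            return float(self.interface_well_depth)
        return float(load_defaults()["interface_well_depth"])


@dataclass(frozen=True)
class SteeringConfig:
    """Opposing axial steering forces.

    ``per_particle_force`` is in the per-atom units of the assay
    (kJ mol^-1 nm^-1); it is applied to *every* bead, along +axis for
    ``opposing_groups[0]`` and -axis for ``opposing_groups[1]``.
    """

    per_particle_force: float = 0.05
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    opposing_groups: tuple[str, str] = ("dimer1", "dimer2")

    def __post_init__(self) -> None:
        if self.per_particle_force < 0:
            raise ValueError("per_particle_force must be >= 0")
        ax = np.asarray(self.axis, dtype=float)
        if not np.isclose(np.linalg.norm(ax), 1.0, atol=1e-6):
            raise ValueError("axis must be a unit vector")
        if set(self.opposing_groups) != {"dimer1", "dimer2"}:
            raise ValueError("opposing_groups must name dimer1 and dimer2")


@dataclass(frozen=True)
class GenotypeFactor:
    """Interface-weakening factor for a genotype label."""

    label: str
    interface_scale: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.interface_scale <= 1.0:
            raise ValueError("interface scale must be in [0, 1]")


GENOTYPE_LABELS = ("WT", "L102E", "L106E", "L102E/L106E")


def genotype_scale(label: str) -> GenotypeFactor:
    """Return the frozen, calibrated interface scale for a genotype.

    Ordering invariant: scale(WT)=1 > scale(L102E) > scale(L106E) >=
    scale(L102E/L106E), mirroring the relative interface stability of the
    wild type, the tolerated surface mutation, the core mutation and the
    double mutation.
    """
    scales = load_defaults()["genotype_scales"]
    if label not in scales:
        raise ValueError(
            f"unknown genotype {label!r}; valid labels: {sorted(scales)}"
        )
    return GenotypeFactor(label=label, interface_scale=float(scales[label]))


def force_to_reduced(force_kj_mol_nm: float) -> float:
    """Convert a per-atom force in kJ mol^-1 nm^-1 to kT(310K)/A per bead."""
    per_bead_kj_mol_A = force_kj_mol_nm * ATOMS_PER_BEAD * 0.1
    return per_bead_kj_mol_A / KT_310_KJ_PER_MOL


# ----------------------------------------------------------------------
# Model construction
# ----------------------------------------------------------------------

def build_tetramer_model(
    params: CGModelParams, genotype: GenotypeFactor | None = None
) -> AssemblyStructure:
    """Build the head-to-head dimer-of-dimers bead model.

    Chains A,B form dimer1 (tips at low z, tails extending to +z); chains
    C,D form dimer2, mirrored so the two 11-bead tips interdigitate around
    z ~ 0 with the marker-residue centroids < 10 A apart (an intact
    interface by the assay's criterion). Residues are numbered in human
    coordinates 101..(100 + beads_per_chain); the marker bead is h.109.
    """
    n = params.beads_per_chain
    b = params.bond_length
    half = params.pairing_distance / 2.0
    overlap = (N_TIP_BEADS - 1) * b  # tips span z in [0, overlap]

    chain_ids: list[str] = []
    resi: list[int] = []
    coords: list[tuple[float, float, float]] = []
    layout = {
        "A": ((-half, 0.0), +1.0, 0.0),
        "B": ((+half, 0.0), +1.0, 0.0),
        "C": ((0.0, -half), -1.0, overlap),
        "D": ((0.0, +half), -1.0, overlap),
    }
    for cid, ((x, y), direction, z0) in layout.items():
        for i in range(n):
            chain_ids.append(cid)
            resi.append(_HUMAN_FIRST_RESIDUE + i)
            coords.append((x, y, z0 + direction * i * b))

    structure = AssemblyStructure(
        chain_ids=chain_ids,
        residue_indices=np.array(resi),
        residue_names=["GLY"] * (4 * n),
        atom_names=["CG"] * (4 * n),
        coords=np.array(coords),
    )
    structure.assign_dimers(
        {"A": "dimer1", "B": "dimer1", "C": "dimer2", "D": "dimer2"},
        marker_residue=_HUMAN_MARKER,
    )
    return structure


# ----------------------------------------------------------------------
# Integration
# ----------------------------------------------------------------------

def _interface_force(
    x1: np.ndarray, x2: np.ndarray, depth: float, r0: float, cutoff: float
) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise flat-ended quartic well between matched tip-bead pairs.

    ``x1`` and ``x2`` hold the two beads of each contact pair, row-matched.
    V(r) = -depth * (1 - s^2)^2 with s = (r - r0)/w, w = cutoff - r0,
    for |r - r0| < w, else 0. Attractive toward r0 from outside, softly
    repulsive inside (the well doubles as an excluded-volume stand-in).
    Returns forces on x1 and x2 rows.
    """
    w = cutoff - r0
    rij = x1 - x2  # (n_pairs, 3)
    r = np.sqrt(np.einsum("ij,ij->i", rij, rij))
    s = (r - r0) / w
    engaged = np.abs(s) < 1.0
    # dV/dr = 4 * depth * s * (1 - s^2) / w
    dVdr = np.where(engaged, 4.0 * depth * s * (1.0 - s * s) / w, 0.0)
    unit = rij / np.maximum(r, 1e-12)[:, None]
    f1 = -dVdr[:, None] * unit
    return f1, -f1


class _ForceField:
    """Precomputed index arrays and force evaluation for the tetramer.

    Coordinates are gathered into chain-major (4, n, 3) layout once per
    step so that all bonded terms are pure slice arithmetic.
    """

    def __init__(
        self,
        structure: AssemblyStructure,
        params: CGModelParams,
        steering: SteeringConfig | None,
        interface_depth: float,
    ):
        self.params = params
        self.depth = interface_depth
        n = params.beads_per_chain
        chains = structure.chains()
        if len(chains) != 4 or structure.n_particles != 4 * n:
            raise ValueError("expected 4 chains of beads_per_chain beads")
        d1 = [c for c in chains if structure.dimer_assignment[c] == "dimer1"]
        d2 = [c for c in chains if structure.dimer_assignment[c] == "dimer2"]
        if len(d1) != 2 or len(d2) != 2:
            raise ValueError("each dimer needs exactly 2 chains")
        # chain-major gather order: dimer1 pair then dimer2 pair
        order = []
        for c in d1 + d2:
            idx = structure.particle_indices(chain=c)
            if len(idx) != n:
                raise ValueError("chains must have beads_per_chain beads each")
            order.append(idx)
        self.order = np.concatenate(order)
        # Interface contact pairs (chain-major frame): tip bead k of each
        # dimer1 chain binds the mirrored tip bead N_TIP_BEADS-1-k of each
        # dimer2 chain — a lock-and-key registry that emulates the
        # structured head-to-head contact and forbids register sliding.
        k = np.arange(N_TIP_BEADS)
        pairs_i, pairs_j = [], []
        for a in (0, 1):  # dimer1 chains
            for c in (2, 3):  # dimer2 chains
                pairs_i.append(a * n + k)
                pairs_j.append(c * n + (N_TIP_BEADS - 1 - k))
        self.pair_i = np.concatenate(pairs_i)
        self.pair_j = np.concatenate(pairs_j)
        # steering (chain-major frame): dimer1 = chains 0,1; dimer2 = 2,3
        if steering is not None and steering.per_particle_force > 0:
            f = force_to_reduced(steering.per_particle_force)
            ax = np.asarray(steering.axis, dtype=float)
            sgn = np.ones((4, n, 1))
            plus = steering.opposing_groups[0]
            if plus == "dimer1":
                sgn[2:] = -1.0
            else:
                sgn[:2] = -1.0
            self.steer = (sgn * (f * ax)).reshape(-1, 3)
        else:
            self.steer = None

    def __call__(self, x: np.ndarray) -> np.ndarray:
        p = self.params
        n = p.beads_per_chain
        xg = x[self.order].reshape(4, n, 3)
        fg = np.zeros_like(xg)
        _harmonic_series(fg, xg, 1, p.bond_length, p.bond_stiffness)
        _harmonic_series(fg, xg, 2, 2.0 * p.bond_length, p.bend_stiffness)
        # paired-chain restraints keep each dimer rigid-ish
        d = xg[[0, 2]] - xg[[1, 3]]
        r = np.sqrt(np.einsum("cij,cij->ci", d, d))
        f = (-p.pairing_stiffness * (r - p.pairing_distance) / np.maximum(r, 1e-12))[
            ..., None
        ] * d
        fg[[0, 2]] += f
        fg[[1, 3]] -= f
        ffl = fg.reshape(-1, 3)
        # head-to-head interface
        if self.depth > 0:
            xf = xg.reshape(-1, 3)
            f1, f2 = _interface_force(
                xf[self.pair_i], xf[self.pair_j], self.depth,
                p.interface_contact, p.interface_cutoff,
            )
            np.add.at(ffl, self.pair_i, f1)
            np.add.at(ffl, self.pair_j, f2)
        if self.steer is not None:
            ffl += self.steer
        # scatter back to structure order
        forces = np.empty_like(x)
        forces[self.order] = ffl
        return forces


def _harmonic_series(
    fg: np.ndarray, xg: np.ndarray, lag: int, rest: float, k: float
) -> None:
    """Add harmonic forces between beads ``lag`` apart along every chain."""
    d = xg[:, lag:] - xg[:, :-lag]
    r = np.sqrt(np.einsum("cij,cij->ci", d, d))
    f = (-k * (r - rest) / np.maximum(r, 1e-12))[..., None] * d
    fg[:, lag:] += f
    fg[:, :-lag] -= f


def simulate(
    model: AssemblyStructure,
    params: CGModelParams,
    steering: SteeringConfig | None = None,
    duration: float = 100.0,
    seed: int | None = None,
    genotype: GenotypeFactor | None = None,
    record_stride: int | None = None,
) -> Trajectory:
    """Run overdamped Brownian dynamics for ``duration`` ns.

    Deterministic given ``seed`` (falls back to ``params.seed``). The
    interface well depth is ``params`` (or the frozen default) scaled by
    the genotype factor. Frames are recorded at a fixed stride chosen to
    keep ~400 frames unless ``record_stride`` is given.

    Raises if the deterministic part of a per-step displacement exceeds
    the bond length, which indicates timestep instability (the stochastic
    part is an unbounded Gaussian, so stability is judged on the drift
    term only).
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    depth = params.resolved_well_depth()
    if genotype is not None:
        depth *= genotype.interface_scale
    ff = _ForceField(model, params, steering, depth)

    dt = params.timestep
    n_steps = max(1, int(round(duration / dt)))
    if record_stride is None:
        record_stride = max(1, n_steps // 400)
    mobility = dt / params.friction
    noise_amp = np.sqrt(2.0 * params.kT * dt / params.friction)

    x = model.coords.copy()
    frames = [x.copy()]
    for step in range(1, n_steps + 1):
        dx = mobility * ff(x)
        max_drift = np.abs(dx).max()
        if max_drift > params.bond_length:
            raise RuntimeError(
                f"per-step drift displacement {max_drift:.2f} A exceeds bond "
                f"length at step {step}; reduce the timestep"
            )
        if noise_amp > 0:
            dx += noise_amp * rng.standard_normal(x.shape)
        x = x + dx
        if step % record_stride == 0:
            frames.append(x.copy())
    return Trajectory(
        coords=np.stack(frames),
        time_per_frame=record_stride * dt,
        structure_ref=model,
    )


def simulate_free_diffusion(
    n_beads: int,
    duration: float,
    params: CGModelParams,
    seed: int | None = None,
    record_stride: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate non-interacting beads (diagnostic for the Einstein relation).

    Returns (times ns, positions (n_frames, n_beads, 3)); beads start at
    the origin and frames are stored every ``record_stride`` steps. Mean
    squared displacement should follow 6 (kT/gamma) t.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    dt = params.timestep
    n_steps = max(1, int(round(duration / dt)))
    noise_amp = np.sqrt(2.0 * params.kT * dt / params.friction)
    x = np.zeros((n_beads, 3))
    frames = [x.copy()]
    kept = [0]
    for k in range(1, n_steps + 1):
        x = x + noise_amp * rng.standard_normal(x.shape)
        if k % record_stride == 0:
            frames.append(x.copy())
            kept.append(k)
    return np.array(kept) * dt, np.stack(frames)
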
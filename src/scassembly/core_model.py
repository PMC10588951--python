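"""Core domain types and I/O for synaptonemal-complex assembly analysis.

This module holds the shared containers used across the package:

* :class:`AssemblyStructure` — a bead/atom model of the SYCP1 alphaN-end
  head-to-head "dimer of dimers" assembly, with chain-to-dimer assignment
  and the marker residue (human L109 / mouse L106) whose interdimer
  distance diagnoses an intact head-to-head interface.
* :class:`Trajectory` — frames x particles x 3 coordinates with time
  metadata, as produced by the coarse-grained simulator or converted from
  external molecular dynamics.
* :class:`ImageStack` / :class:`Trace` — superresolution-style z-stacks and
  chromosome-axis polylines for the imaging stage.
* :class:`CountTable2x2` — dichotomized per-genotype tubule counts for
  exact testing.

Units: coordinates are Angstrom throughout the structural code, image
distances are nm, z-spacing is um; conversions happen only at reporting
boundaries. Residue indices are 1-based (PDB/UniProt convention); particle
arrays are 0-based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np

__all__ = [
    "AssemblyStructure",
    "Trajectory",
    "ImageStack",
    "Trace",
    "CountTable2x2",
    "read_pdb",
    "write_pdb",
    "read_xyz",
    "write_xyz",
    "sequence_identity",
    "SequenceIdentity",
    "human_to_mouse_residue",
    "mouse_to_human_residue",
    "read_fasta",
    "HUMAN_ALPHA_N_SPAN",
    "MOUSE_ALPHA_N_SPAN",
    "HUMAN_MARKER_RESIDUE",
    "MOUSE_MARKER_RESIDUE",
    "SPECIES_OFFSET",
]

# Human SYCP1 alphaN-end spans residues 101-175; the mouse orthologue spans
# 98-172, i.e. mouse numbering = human numbering - 3.  The head-to-head
# marker residue is h.L109 (m.L106); the alphaN tip is h.101-111.
HUMAN_ALPHA_N_SPAN = (101, 175)
MOUSE_ALPHA_N_SPAN = (98, 172)
HUMAN_MARKER_RESIDUE = 109
MOUSE_MARKER_RESIDUE = 106
SPECIES_OFFSET = 3  # mouse index = human index - SPECIES_OFFSET
ALPHA_N_TIP_SPAN = (101, 111)  # human numbering

DIMER_LABELS = ("dimer1", "dimer2")


def human_to_mouse_residue(h_index: int) -> int:
    """Map a human SYCP1 residue index in the alphaN-end to mouse numbering."""
    lo, hi = HUMAN_ALPHA_N_SPAN
    if not lo <= h_index <= hi:
        raise ValueError(
            f"human residue {h_index} outside alphaN-end span {lo}-{hi}"
        )
    return h_index - SPECIES_OFFSET


def mouse_to_human_residue(m_index: int) -> int:
    """Inverse of :func:`human_to_mouse_residue`."""
    lo, hi = MOUSE_ALPHA_N_SPAN
    if not lo <= m_index <= hi:
        raise ValueError(
            f"mouse residue {m_index} outside alphaN-end span {lo}-{hi}"
        )
    return m_index + SPECIES_OFFSET


@dataclass
class AssemblyStructure:
    """Particle model of a (tetrameric) assembly.

    Parameters are parallel arrays over particles, in file/build order.
    ``dimer_assignment`` maps chain id -> "dimer1"/"dimer2" and may be left
    unset (``None``) until assigned; ``marker_residue`` is the 1-based
    residue index of the head-to-head marker in this structure's numbering.
    """

    chain_ids: list[str]
    residue_indices: np.ndarray
    residue_names: list[str]
    atom_names: list[str]
    coords: np.ndarray
    dimer_assignment: dict[str, str] | None = None
    marker_residue: int | None = None
    species_offset: int = SPECIES_OFFSET

    def __post_init__(self) -> None:
        self.residue_indices = np.asarray(self.residue_indices, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.chain_ids)
        if not (
            len(self.residue_names) == len(self.atom_names) == n
            and self.residue_indices.shape == (n,)
            and self.coords.shape == (n, 3)
        ):
            raise ValueError("particle arrays have inconsistent lengths")
        if n == 0:
            raise ValueError("no atoms")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if self.dimer_assignment is not None:
            self._check_dimer_assignment()

    # -- invariants -----------------------------------------------------
    def _check_dimer_assignment(self) -> None:
        assert self.dimer_assignment is not None
        chains = set(self.chain_ids)
        assigned = set(self.dimer_assignment)
        if assigned != chains:
            raise ValueError(
                f"dimer_assignment chains {sorted(assigned)} do not match "
                f"structure chains {sorted(chains)}"
            )
        labels = set(self.dimer_assignment.values())
        if not labels <= set(DIMER_LABELS):
            raise ValueError(f"dimer labels must be in {DIMER_LABELS}")
        for label in DIMER_LABELS:
            if label not in labels:
                raise ValueError(f"dimer {label!r} has no chains")
        if self.marker_residue is not None:
            for ch in chains:
                mask = (np.array(self.chain_ids) == ch) & (
                    self.residue_indices == self.marker_residue
                )
                if not mask.any():
                    raise ValueError(
                        f"marker residue {self.marker_residue} absent from chain {ch}"
                    )

    @property
    def n_particles(self) -> int:
        return len(self.chain_ids)

    def chains(self) -> list[str]:
        """Unique chain ids in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.chain_ids:
            seen.setdefault(c)
        return list(seen)

    def particle_indices(
        self, chain: str | None = None, residue: int | None = None
    ) -> np.ndarray:
        """0-based indices of particles matching the selection."""
        mask = np.ones(self.n_particles, dtype=bool)
        if chain is not None:
            mask &= np.array(self.chain_ids) == chain
        if residue is not None:
            mask &= self.residue_indices == residue
        return np.flatnonzero(mask)

    def dimer_particles(self, dimer: str) -> np.ndarray:
        """0-based indices of all particles belonging to one dimer."""
        if self.dimer_assignment is None:
            raise ValueError("dimer_assignment is unset")
        chains = [c for c, d in self.dimer_assignment.items() if d == dimer]
        if not chains:
            raise ValueError(f"no chains assigned to {dimer!r}")
        mask = np.isin(np.array(self.chain_ids), chains)
        return np.flatnonzero(mask)

    def assign_dimers(
        self, assignment: dict[str, str], marker_residue: int | None = None
    ) -> None:
        self.dimer_assignment = dict(assignment)
        if marker_residue is not None:
            self.marker_residue = marker_residue
        self._check_dimer_assignment()


@dataclass
class Trajectory:
    """Ordered coordinate frames with uniform time spacing.

    ``coords`` has shape (n_frames, n_particles, 3) in Angstrom;
    ``time_per_frame`` is ns between stored frames (first frame at t=0).
    """

    coords: np.ndarray
    time_per_frame: float
    structure_ref: AssemblyStructure | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (frames, particles, 3)")
        if self.coords.shape[0] == 0:
            raise ValueError("trajectory has no frames")
        if self.time_per_frame <= 0:
            raise ValueError("time_per_frame must be > 0")
        if (
            self.structure_ref is not None
            and self.structure_ref.n_particles != self.coords.shape[1]
        ):
            raise ValueError(
                "structure_ref particle count does not match trajectory"
            )

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_particles(self) -> int:
        return self.coords.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Frame times in ns, starting at 0."""
        return np.arange(self.n_frames) * self.time_per_frame


@dataclass
class ImageStack:
    """Single-channel z-stack. ``voxels`` is (z, y, x), non-negative."""

    voxels: np.ndarray
    pixel_size_nm: float
    z_step_um: float = 0.1

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3 or self.voxels.shape[0] < 1:
            raise ValueError("voxels must be a (z, y, x) array with >= 1 slice")
        if np.any(self.voxels < 0):
            raise ValueError("voxel intensities must be non-negative")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be > 0")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]


@dataclass
class Trace:
    """Chromosome-axis polyline in 0-based pixel coordinates (x=col, y=row)."""

    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("trace points must be an (N, 2) array")
        if self.points.shape[0] < 2:
            raise ValueError("trace needs at least 2 points")

    def check_inside(self, image_shape: tuple[int, int]) -> None:
        h, w = image_shape
        x, y = self.points[:, 0], self.points[:, 1]
        if (x < 0).any() or (y < 0).any() or (x > w - 1).any() or (y > h - 1).any():
            raise ValueError("trace leaves image bounds")


@dataclass
class CountTable2x2:
    """2x2 contingency table: rows = genotypes, cols = (<threshold, >=threshold)."""

    table: np.ndarray
    row_labels: tuple[str, str] = ("genotype_a", "genotype_b")
    col_labels: tuple[str, str] = ("below", "at_or_above")

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=int)
        if self.table.shape != (2, 2):
            raise ValueError("table must be 2x2")
        if (self.table < 0).any():
            raise ValueError("table entries must be non-negative")

    def check_margins(self) -> None:
        if (self.table.sum(axis=0) == 0).any() or (self.table.sum(axis=1) == 0).any():
            raise ValueError("both margins must be positive for testing")


# ----------------------------------------------------------------------
# PDB I/O (minimal ATOM/HETATM subset; first MODEL only), backed by gemmi.
# ----------------------------------------------------------------------

def read_pdb(path: str | Path) -> AssemblyStructure:
    """Read ATOM/HETATM records of the first model into an AssemblyStructure.

    Chain ids, residue identity and coordinates are preserved in file
    order; altlocs beyond the first and models beyond the first are
    ignored. ``dimer_assignment`` is left unset.
    """
    import gemmi

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_pdb(str(path))
    except Exception as exc:  # malformed coordinate fields etc.
        raise ValueError(f"unreadable PDB file {path}: {exc}") from exc
    chain_ids: list[str] = []
    resi: list[int] = []
    resn: list[str] = []
    names: list[str] = []
    xyz: list[tuple[float, float, float]] = []
    if len(st) == 0:
        raise ValueError("no atoms")
    model = st[0]
    for chain in model:
        for res in chain:
            for atom in res:
                if atom.altloc not in ("\x00", "", "A"):
                    continue
                chain_ids.append(chain.name)
                resi.append(res.seqid.num)
                resn.append(res.name)
                names.append(atom.name)
                xyz.append((atom.pos.x, atom.pos.y, atom.pos.z))
    if not chain_ids:
        raise ValueError("no atoms")
    return AssemblyStructure(
        chain_ids=chain_ids,
        residue_indices=np.array(resi),
        residue_names=resn,
        atom_names=names,
        coords=np.array(xyz),
    )


def write_pdb(structure: AssemblyStructure, path: str | Path) -> Path:
    """Write the structure as plain ATOM records (one model)."""
    import gemmi

    # gemmi's add_* methods copy, so build bottom-up: fully populate each
    # residue/chain before inserting it.
    grouped: dict[str, dict[int, tuple[str, list[int]]]] = {}
    chain_order: list[str] = []
    for i in range(structure.n_particles):
        cid = structure.chain_ids[i]
        if cid not in grouped:
            grouped[cid] = {}
            chain_order.append(cid)
        ri = int(structure.residue_indices[i])
        grouped[cid].setdefault(ri, (structure.residue_names[i], []))[1].append(i)

    st = gemmi.Structure()
    model = gemmi.Model("1")
    for cid in chain_order:
        chain = gemmi.Chain(cid)
        for ri, (rname, idxs) in grouped[cid].items():
            res = gemmi.Residue()
            res.name = rname
            res.seqid = gemmi.SeqId(ri, " ")
            res.het_flag = "A"  # standard ATOM record
            for i in idxs:
                atom = gemmi.Atom()
                atom.name = structure.atom_names[i]
                x, y, z = structure.coords[i]
                atom.pos = gemmi.Position(float(x), float(y), float(z))
                atom.element = gemmi.Element("C")
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    path = Path(path)
    st.write_pdb(str(path))
    return path


# ----------------------------------------------------------------------
# Multi-frame XYZ dialect: count line, comment line carrying "t= <ns>",
# then "name x y z" per particle.
# ----------------------------------------------------------------------

def write_xyz(traj: Trajectory, path: str | Path) -> Path:
    """Write a trajectory in the package's multi-frame XYZ dialect."""
    path = Path(path)
    n = traj.n_particles
    names = (
        traj.structure_ref.atom_names
        if traj.structure_ref is not None
        else ["X"] * n
    )
    times = traj.times
    with open(path, "w") as fh:
        for k in range(traj.n_frames):
            fh.write(f"{n}\n")
            fh.write(f"frame {k} t= {times[k]:.6f} ns\n")
            frame = traj.coords[k]
            for name, (x, y, z) in zip(names, frame):
                fh.write(f"{name} {x:.4f} {y:.4f} {z:.4f}\n")
    return path


def read_xyz(
    path: str | Path, structure_ref: AssemblyStructure | None = None
) -> Trajectory:
    """Read a multi-frame XYZ file written by :func:`write_xyz`.

    Frame times are taken from the ``t= <value>`` token of the comment
    line; frames must share a particle count.
    """
    path = Path(path)
    frames: list[np.ndarray] = []
    times: list[float] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    frame_no = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise ValueError(
                f"expected particle count at line {i + 1} of {path}"
            ) from exc
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        t = _parse_time_token(comment)
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise ValueError(
                f"frame {frame_no} truncated: expected {n} particles"
            )
        coords = np.array(
            [[float(v) for v in ln.split()[1:4]] for ln in block]
        )
        if frames and coords.shape != frames[0].shape:
            raise ValueError(
                f"frame {frame_no} has {coords.shape[0]} particles, "
                f"expected {frames[0].shape[0]}"
            )
        frames.append(coords)
        times.append(t if t is not None else float(frame_no))
        i += 2 + n
        frame_no += 1
    if not frames:
        raise ValueError("empty trajectory file")
    if len(times) > 1:
        dt = times[1] - times[0]
        if dt <= 0:
            raise ValueError("frame times must be increasing")
    else:
        dt = 1.0
    return Trajectory(
        coords=np.stack(frames), time_per_frame=dt, structure_ref=structure_ref
    )


def _parse_time_token(comment: str) -> float | None:
    tokens = comment.split()
    for j, tok in enumerate(tokens):
        if tok == "t=" and j + 1 < len(tokens):
            return float(tokens[j + 1])
        if tok.startswith("t=") and len(tok) > 2:
            return float(tok[2:])
    return None


# ----------------------------------------------------------------------
# Sequences
# ----------------------------------------------------------------------

class SequenceIdentity(NamedTuple):
    """Percent identity of a gapless positional alignment.

    ``percent`` is the exact ratio x 100; ``percent_int`` truncates toward
    zero (the integer convention used when reporting, e.g. 62/75 -> 82).
    """

    percent: float
    percent_int: int
    n_identical: int
    length: int


def sequence_identity(seq_a: str, seq_b: str) -> SequenceIdentity:
    """Percent identity between two equal-length residue strings.

    Symmetric in its arguments; comparison is case-insensitive.
    """
    if len(seq_a) == 0 or len(seq_b) == 0:
        raise ValueError("empty sequence")
    if len(seq_a) != len(seq_b):
        raise ValueError(
            f"sequences must have equal length ({len(seq_a)} vs {len(seq_b)})"
        )
    a = seq_a.upper()
    b = seq_b.upper()
    n_same = sum(1 for x, y in zip(a, b) if x == y)
    pct = 100.0 * n_same / len(a)
    return SequenceIdentity(pct, math.trunc(pct), n_same, len(a))


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into {record id: sequence}."""
    from Bio import SeqIO

    records = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records
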
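"""Trajectory metrics for the steered-dissociation assay.

Implements the quantities used to read out head-to-head interface
stability from a trajectory: optimal-superposition RMSD (Kabsch), per-
residue RMSF about the mean structure, the interdimer distance between the
marker residues (h.L109/m.L106) of the two opposing dimers, and the
intact / loosened / dissociated classification with its disruption time.

Classification contract: the interface counts as intact while the
interdimer distance stays below ``intact_threshold`` (10 A); dissociation
is a crossing of ``dissociated_threshold`` (default 30 A) after which the
smoothed distance never returns below the intact threshold; a persistent
excursion above the intact threshold that never reaches the dissociated
threshold is "loosened". The marker distance uses the centroid of all
marker-residue particles of each dimer (both chain copies), since the
assay does not name a specific atom. Disruption times are reported at
frame resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_model import AssemblyStructure, Trajectory

__all__ = [
    "DissociationResult",
    "kabsch_superpose",
    "rmsd_series",
    "rmsf",
    "interdimer_distance",
    "interdimer_distance_series",
    "detect_dissociation",
]

INTACT_THRESHOLD_A = 10.0
DISSOCIATED_THRESHOLD_A = 30.0
PERSISTENCE_WINDOW = 5


@dataclass
class DissociationResult:
    """Outcome of the dissociation classifier for one trajectory."""

    status: str  # intact | loosened | dissociated
    disruption_time: float | None  # ns, set iff dissociated
    times: np.ndarray  # ns
    distances: np.ndarray  # A
    intact_threshold: float = INTACT_THRESHOLD_A
    dissociated_threshold: float = DISSOCIATED_THRESHOLD_A
    persistence_window: int = PERSISTENCE_WINDOW

    def __post_init__(self) -> None:
        if self.status not in ("intact", "loosened", "dissociated"):
            raise ValueError(f"bad status {self.status!r}")
        if (self.status == "dissociated") != (self.disruption_time is not None):
            raise ValueError("disruption_time set iff status is dissociated")
        self.times = np.asarray(self.times, dtype=float)
        self.distances = np.asarray(self.distances, dtype=float)
        if self.distances.size == 0:
            raise ValueError("empty distance series")
        if (self.distances < 0).any():
            raise ValueError("distances must be >= 0")

    def to_dict(self) -> dict:
        return {
            "status": self.status,
            "disruption_time_ns": self.disruption_time,
            "intact_threshold_A": self.intact_threshold,
            "dissociated_threshold_A": self.dissociated_threshold,
            "persistence_window": self.persistence_window,
            "times_ns": self.times.tolist(),
            "distances_A": self.distances.tolist(),
        }


# ----------------------------------------------------------------------
# Superposition
# ----------------------------------------------------------------------

def kabsch_superpose(
    X: np.ndarray, Y: np.ndarray, weights: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal proper-rotation superposition of X onto Y.

    Returns (R, t, rmsd) such that ``X @ R.T + t`` minimizes the weighted
    RMSD to Y, with det(R) = +1 (reflections excluded).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("X and Y must be matching (N, 3) arrays")
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 particles for superposition")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or (w < 0).any() or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        w = w / w.sum()
    xc = (w[:, None] * X).sum(axis=0)
    yc = (w[:, None] * Y).sum(axis=0)
    X0 = X - xc
    Y0 = Y - yc
    H = (w[:, None] * X0).T @ Y0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = yc - R @ xc
    diff = X0 @ R.T - Y0
    rmsd = float(np.sqrt((w * np.einsum("ij,ij->i", diff, diff)).sum()))
    return R, t, rmsd


def rmsd_series(
    traj: Trajectory,
    reference_frame: int = 0,
    selection: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """(times, RMSD) of each frame against a reference frame.

    Each frame is superposed onto the reference over ``selection`` (all
    particles by default) before the RMSD is taken over that selection.
    """
    if not 0 <= reference_frame < traj.n_frames:
        raise IndexError(f"reference frame {reference_frame} out of range")
    sel = _resolve_selection(selection, traj.n_particles)
    ref = traj.coords[reference_frame][sel]
    out = np.empty(traj.n_frames)
    for k in range(traj.n_frames):
        _, _, out[k] = kabsch_superpose(traj.coords[k][sel], ref)
    return traj.times, out


def rmsf(
    traj: Trajectory,
    selection: np.ndarray | None = None,
    align_to_mean: bool = True,
    max_iter: int = 5,
) -> np.ndarray:
    """Per-particle RMS fluctuation about the time-mean position.

    With ``align_to_mean`` each frame is superposed onto the mean
    structure (the mean is recomputed and alignment repeated up to
    ``max_iter`` rounds, a standard fixed-point scheme).
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    sel = _resolve_selection(selection, traj.n_particles)
    frames = traj.coords[:, sel, :].copy()
    if align_to_mean:
        mean = frames[0]
        for _ in range(max_iter):
            aligned = np.empty_like(frames)
            for k in range(frames.shape[0]):
                R, t, _ = kabsch_superpose(frames[k], mean)
                aligned[k] = frames[k] @ R.T + t
            new_mean = aligned.mean(axis=0)
            if np.allclose(new_mean, mean, atol=1e-10):
                frames = aligned
                break
            mean = new_mean
            frames = aligned
    mean = frames.mean(axis=0)
    dev = frames - mean
    return np.sqrt(np.einsum("kij,kij->ki", dev, dev).mean(axis=0))


def _resolve_selection(selection: np.ndarray | None, n: int) -> np.ndarray:
    if selection is None:
        return np.arange(n)
    sel = np.asarray(selection)
    if sel.dtype == bool:
        sel = np.flatnonzero(sel)
    if sel.size == 0:
        raise ValueError("empty selection")
    return sel


# ----------------------------------------------------------------------
# Interdimer distance & dissociation
# ----------------------------------------------------------------------

def interdimer_distance(frame: np.ndarray, structure: AssemblyStructure) -> float:
    """Distance between the marker-residue centroids of the two dimers.

    The centroid is over all particles of the marker residue in every
    chain of the dimer; invariant under global rigid motion.
    """
    if structure.dimer_assignment is None or structure.marker_residue is None:
        raise ValueError("structure needs dimer_assignment and marker_residue")
    frame = np.asarray(frame, dtype=float)
    centroids = []
    for dimer in ("dimer1", "dimer2"):
        idx = np.intersect1d(
            structure.dimer_particles(dimer),
            structure.particle_indices(residue=structure.marker_residue),
        )
        if idx.size == 0:
            raise ValueError(f"marker residue absent from {dimer}")
        centroids.append(frame[idx].mean(axis=0))
    return float(np.linalg.norm(centroids[0] - centroids[1]))


def interdimer_distance_series(
    traj: Trajectory, structure: AssemblyStructure | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """(times ns, interdimer distance A) over all frames."""
    structure = structure or traj.structure_ref
    if structure is None:
        raise ValueError("no structure metadata available")
    d = np.array(
        [interdimer_distance(traj.coords[k], structure) for k in range(traj.n_frames)]
    )
    return traj.times, d


def _centered_moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with shrinking windows at the edges."""
    if window <= 1:
        return x.astype(float)
    n = x.size
    c = np.concatenate([[0.0], np.cumsum(x, dtype=float)])
    half = window // 2
    lo = np.clip(np.arange(n) - half, 0, n)
    hi = np.clip(np.arange(n) + half + 1, 0, n)
    return (c[hi] - c[lo]) / (hi - lo)


def detect_dissociation(
    times: np.ndarray,
    distances: np.ndarray,
    intact_threshold: float = INTACT_THRESHOLD_A,
    dissociated_threshold: float = DISSOCIATED_THRESHOLD_A,
    persistence_window: int = PERSISTENCE_WINDOW,
) -> DissociationResult:
    """Classify a distance series as intact, loosened or dissociated.

    Persistence is judged on a centered moving average of width
    ``persistence_window``; the disruption time is the first raw crossing
    of the dissociated threshold whose smoothed tail never returns below
    the intact threshold.
    """
    times = np.asarray(times, dtype=float)
    distances = np.asarray(distances, dtype=float)
    if times.size == 0 or distances.size != times.size:
        raise ValueError("times and distances must be matching non-empty arrays")
    if times.size > 1 and np.any(np.diff(times) <= 0):
        raise ValueError("time stamps must be strictly increasing")
    smooth = _centered_moving_average(distances, persistence_window)
    # suffix minimum of the smoothed series: tail_min[i] = min(smooth[i:])
    tail_min = np.minimum.accumulate(smooth[::-1])[::-1]

    status = "intact"
    disruption_time: float | None = None
    crossing = np.flatnonzero(distances >= dissociated_threshold)
    for i in crossing:
        if tail_min[i] >= intact_threshold:
            status = "dissociated"
            disruption_time = float(times[i])
            break
    if status != "dissociated":
        above = np.flatnonzero(smooth > intact_threshold)
        if above.size and tail_min[above[0]] > intact_threshold:
            status = "loosened"
    return DissociationResult(
        status=status,
        disruption_time=disruption_time,
        times=times,
        distances=distances,
        intact_threshold=intact_threshold,
        dissociated_threshold=dissociated_threshold,
        persistence_window=persistence_window,
    )
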
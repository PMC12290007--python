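"""Conformational clustering of adsorbed peptide states.

Bound-state frames are pairwise superposed (Kabsch least-squares fit) and
clustered with the iterative GROMOS neighbor-count algorithm: the frame
with the most neighbors within an RMSD cutoff seeds a cluster, it and its
neighbors are removed, and the procedure repeats until every frame is
assigned.  Note that fitted RMSD is not a metric (no triangle inequality),
which is why clustering works on the explicit pairwise matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .observables import BindingProfile
from .topology import SystemTopology, TrajectoryFrame


@dataclass
class ClusterResult:
    """GROMOS cluster assignments over a set of frames.

    ``members`` holds per-cluster frame positions (into the clustered frame
    list), largest cluster first; ``frame_ids`` maps those positions to the
    caller's original frame indices when provided.
    """

    members: list[np.ndarray]
    centroids: np.ndarray        # one medoid frame position per cluster
    populations: np.ndarray      # % of clustered frames, non-increasing
    cutoff: float                # nm
    selection: str = "peptide heavy atoms"
    frame_ids: np.ndarray | None = None

    @property
    def n_clusters(self) -> int:
        return len(self.members)

    def labels(self) -> np.ndarray:
        """Cluster id (0-based, by decreasing size) per clustered frame."""
        n = sum(len(m) for m in self.members)
        lab = np.empty(n, dtype=int)
        for cid, m in enumerate(self.members):
            lab[m] = cid
        return lab


def kabsch_rmsd(X: np.ndarray, Y: np.ndarray,
                weights: np.ndarray | None = None) -> float:
    """RMSD (nm) after optimal least-squares superposition of Y onto X.

    The rotation is the Kabsch solution with a proper-rotation constraint
    (determinant +1), so mirror images are not superposed onto each other.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise ValueError(f"coordinate shapes must match and be (N, 3): {X.shape} vs {Y.shape}")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 atoms for superposition")
    if weights is None:
        w = np.full(X.shape[0], 1.0 / X.shape[0])
    else:
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()
    xc = X - (w @ X)
    yc = Y - (w @ Y)
    H = (xc * w[:, None]).T @ yc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    # rotation mapping yc onto xc; residual evaluated explicitly so that an
    # exact rigid transform yields an RMSD at machine precision rather than
    # the square root of a cancellation error
    R = (U * np.array([1.0, 1.0, d])) @ Vt
    resid = xc - yc @ R.T
    return float(np.sqrt((w * (resid ** 2).sum(axis=1)).sum()))


def extract_bound_frames(frames: list[TrajectoryFrame], profile: BindingProfile
                         ) -> tuple[list[TrajectoryFrame], np.ndarray]:
    """The adsorbed-state (bound) frames and their original indices.

    Returns an empty selection (with a warning) when the peptide never binds.
    """
    frames = list(frames)
    if len(frames) != profile.n_frames:
        raise ValueError(f"{len(frames)} frames but profile has {profile.n_frames}")
    idx = np.flatnonzero(profile.bound)
    if idx.size == 0:
        import warnings
        warnings.warn("no bound frames to extract")
    return [frames[i] for i in idx], idx


def rmsd_matrix(frames: list[TrajectoryFrame], selection: np.ndarray,
                stride: int = 1, topology: SystemTopology | None = None,
                unwrap: bool = True, weights: np.ndarray | None = None
                ) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise fitted-RMSD matrix over a selection of atoms.

    Frames are optionally made whole first (the fit is meaningless on
    wrapped coordinates).  Returns (matrix, kept_frame_positions); the
    matrix is symmetric with a zero diagonal.  Vectorised: per-pair 3x3
    cross-covariances via einsum and a batched SVD.
    """
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise ValueError("empty atom selection for RMSD")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    kept = np.arange(0, len(frames), stride)
    if kept.size < 2:
        raise ValueError("need at least 2 frames after stride")

    if unwrap:
        if topology is None:
            raise ValueError("topology required to unwrap frames")
        from .observables import unwrap_peptide
        from .topology import peptide_bond_list
        bonds = peptide_bond_list(topology)
        coords = np.stack([unwrap_peptide(frames[i], topology, bonds=bonds)[selection]
                           for i in kept])
    else:
        coords = np.stack([frames[i].coords[selection] for i in kept])

    n_atoms = selection.size
    if weights is None:
        w = np.full(n_atoms, 1.0 / n_atoms)
    else:
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()
    coords = coords - np.einsum("n,fni->fi", w, coords)[:, None, :]
    wc = coords * w[None, :, None]
    H = np.einsum("fni,gnj->fgij", wc, coords)          # (F, F, 3, 3)
    U, S, Vt = np.linalg.svd(H)
    det = np.linalg.det(np.einsum("fgij,fgjk->fgik", U, Vt))
    S[..., -1] *= np.sign(det)
    sq = np.einsum("n,fni->f", w, coords ** 2)
    msd = sq[:, None] + sq[None, :] - 2.0 * S.sum(axis=-1)
    mat = np.sqrt(np.maximum(msd, 0.0))
    mat = 0.5 * (mat + mat.T)   # remove SVD round-off asymmetry
    np.fill_diagonal(mat, 0.0)
    return mat, kept


def gromos_cluster(matrix: np.ndarray, cutoff: float,
                   frame_ids: np.ndarray | None = None,
                   selection: str = "peptide heavy atoms") -> ClusterResult:
    """Iterative GROMOS clustering of a pairwise RMSD matrix.

    At each step the unassigned frame with the largest number of unassigned
    neighbors within ``cutoff`` (RMSD <= cutoff; ties broken by lowest frame
    index) becomes a cluster center; it and its neighbors form the cluster
    and are removed.  Singleton clusters are allowed.  Output clusters are
    ordered by size (descending), ties by center index.
    """
    M = np.asarray(matrix, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("matrix must be square")
    if np.isnan(M).any():
        raise ValueError("NaN in RMSD matrix")
    if not np.allclose(M, M.T, atol=1e-8):
        raise ValueError("matrix must be symmetric")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")

    n = M.shape[0]
    neighbor = (M <= cutoff)
    np.fill_diagonal(neighbor, True)
    alive = np.ones(n, dtype=bool)
    raw: list[tuple[int, np.ndarray]] = []
    while alive.any():
        counts = (neighbor & alive[None, :]).sum(axis=1)
        counts[~alive] = -1
        center = int(np.argmax(counts))     # argmax takes the lowest index on ties
        members = np.flatnonzero(neighbor[center] & alive)
        raw.append((center, members))
        alive[members] = False
    raw.sort(key=lambda cm: (-len(cm[1]), cm[0]))
    members = [m for _, m in raw]
    centroids = np.array([c for c, _ in raw], dtype=int)
    populations = np.array([100.0 * len(m) / n for m in members])
    return ClusterResult(members=members, centroids=centroids,
                         populations=populations, cutoff=cutoff,
                         selection=selection,
                         frame_ids=None if frame_ids is None else np.asarray(frame_ids))


def cluster_summary(result: ClusterResult, profile: BindingProfile,
                    population_floor_percent: float = 10.0) -> pd.DataFrame:
    """Per-cluster summary for clusters above a population floor.

    Rows: cluster id, population %, mean SSD, mean EED (over member
    frames), and the centroid frame's timestamp.  ``result.frame_ids``
    maps clustered frames back into the profile's frame axis.
    """
    ids = result.frame_ids
    if ids is None:
        ids = np.arange(sum(len(m) for m in result.members))
    rows = []
    for cid, (memb, cen, pop) in enumerate(zip(result.members, result.centroids,
                                               result.populations), start=1):
        if pop <= population_floor_percent:
            continue
        fids = ids[memb]
        rows.append({"cluster": cid, "population_percent": pop,
                     "ssd_nm": float(profile.ssd[fids].mean()),
                     "eed_nm": float(profile.eed[fids].mean()),
                     "representative_time_ps": float(profile.times[ids[cen]])})
    return pd.DataFrame(rows, columns=["cluster", "population_percent", "ssd_nm",
                                       "eed_nm", "representative_time_ps"])


def peptide_heavy_selection(topology: SystemTopology) -> np.ndarray:
    """Peptide non-hydrogen atom indices — the default clustering selection."""
    pep = topology.peptide_indices
    elems = np.asarray(topology.elements)
    return pep[elems[pep] != "H"]


def write_assignments_tsv(result: ClusterResult, profile: BindingProfile, path) -> None:
    """Per-frame cluster assignment TSV: frame_id, time_ps, cluster_id."""
    ids = result.frame_ids
    if ids is None:
        ids = np.arange(sum(len(m) for m in result.members))
    labels = result.labels()
    with open(path, "w") as fh:
        fh.write("frame_id\ttime_ps\tcluster_id\n")
        for pos, lab in enumerate(labels):
            fid = int(ids[pos])
            fh.write(f"{fid}\t{profile.times[fid]:.4f}\t{lab + 1}\n")
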
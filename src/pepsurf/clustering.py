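"""Conformational clustering of peptide ensembles.

Implements greedy neighbour-count clustering over backbone RMSD (the Daura
algorithm): repeatedly take the conformation with the most neighbours within
the cut-off (inclusive), form a cluster from it and its neighbours, remove
them, and repeat.  The centroid of each cluster is the max-neighbour member
structure itself, not a coordinate average.  Ties on neighbour count are
broken by the lowest frame index, so the result is a deterministic partition
of the ensemble.

RMSD is computed after least-squares superposition by default (Kabsch
rotation with the determinant correction that forbids reflections), matching
the reference gmx-cluster behaviour; set ``fit=False`` for raw positional
RMSD.  Cross-variant similarity compares the centroids of the top-k most
populated clusters of two ensembles: a pair is *matched* at RMSD <= 2.0 A and
*near-matched* strictly between 2.0 and 2.5 A.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .errors import InputError
from .trajectory import Trajectory, partition_atoms

__all__ = [
    "Conformation",
    "Cluster",
    "ClusterResult",
    "MatchPair",
    "MatchReport",
    "backbone_rmsd",
    "kabsch_rotation",
    "pairwise_rmsd_matrix",
    "daura_cluster",
    "daura_cluster_from_matrix",
    "cross_cluster_match",
    "extract_backbone",
    "DEFAULT_BACKBONE_ATOMS",
    "MATCH_CUTOFF",
    "NEAR_MATCH_CUTOFF",
]

#: Backbone selection used when pulling conformations out of a trajectory.
#: Carbonyl O excluded by default; pass your own selection to include it.
DEFAULT_BACKBONE_ATOMS = ("N", "CA", "C")

MATCH_CUTOFF = 2.0  # A, centroid pairs at or below are "matched"
NEAR_MATCH_CUTOFF = 2.5  # A, strictly below is "near-matched"

MATCHED = "matched"
NEAR_MATCHED = "near-matched"
UNMATCHED = "unmatched"


@dataclass(frozen=True)
class Conformation:
    """Backbone coordinates of one frame over a fixed atom selection (Angstrom)."""

    coordinates: np.ndarray
    frame_index: int = 0

    def __post_init__(self):
        coords = np.asarray(self.coordinates, dtype=float)
        object.__setattr__(self, "coordinates", coords)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise InputError(f"coordinates must be (m, 3), got {coords.shape}")
        if not np.all(np.isfinite(coords)):
            raise InputError("non-finite coordinates in conformation")

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]


def kabsch_rotation(moving: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Optimal proper rotation (3x3) aligning centred ``moving`` onto centred ``target``.

    The determinant correction flips the smallest singular direction when the
    raw solution would be a reflection.
    """
    H = moving.T @ target
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def backbone_rmsd(a: Conformation, b: Conformation, fit: bool = True) -> float:
    """RMSD (Angstrom) between two conformations, after optimal superposition if ``fit``."""
    if a.n_atoms != b.n_atoms:
        raise InputError(
            f"atom-count mismatch: {a.n_atoms} vs {b.n_atoms}"
        )
    if fit and a.n_atoms < 3:
        raise InputError("fitting needs at least 3 atoms")
    P = a.coordinates
    Q = b.coordinates
    if fit:
        P = P - P.mean(axis=0)
        Q = Q - Q.mean(axis=0)
        P = P @ kabsch_rotation(P, Q).T
    return float(np.sqrt(((P - Q) ** 2).sum(axis=1).mean()))


def pairwise_rmsd_matrix(
    ensemble: list[Conformation], fit: bool = True
) -> np.ndarray:
    """Symmetric (n, n) matrix of pairwise backbone RMSDs."""
    n = len(ensemble)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = backbone_rmsd(ensemble[i], ensemble[j], fit=fit)
    return D


@dataclass(frozen=True)
class Cluster:
    """One cluster: the centroid frame and its members (ensemble positions)."""

    centroid: int
    members: tuple[int, ...]

    @property
    def population(self) -> int:
        return len(self.members)


@dataclass
class ClusterResult:
    """Partition of an ensemble into clusters, ordered by decreasing population.

    ``centroid_coordinates`` (when present) carries the centroid structures so
    two results can be cross-matched without re-threading the ensembles.
    """

    clusters: list[Cluster]
    cutoff: float
    n_frames: int
    centroid_coordinates: list[Conformation] | None = field(default=None, repr=False)

    def populations(self) -> list[int]:
        return [c.population for c in self.clusters]

    def assignments(self) -> np.ndarray:
        """Cluster id (0-based rank) per ensemble position."""
        out = np.full(self.n_frames, -1, dtype=int)
        for cid, cluster in enumerate(self.clusters):
            out[list(cluster.members)] = cid
        return out

    def to_tsv(self, path: str | os.PathLike, header_lines: list[str] | None = None):
        labels = self.assignments()
        centroid_of = {cid: c.centroid for cid, c in enumerate(self.clusters)}
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            fh.write(f"# cutoff_angstrom = {self.cutoff}\n")
            fh.write(f"# n_clusters = {len(self.clusters)}\n")
            fh.write("frame\tcluster\tcentroid_frame\n")
            for frame, cid in enumerate(labels):
                fh.write(f"{frame}\t{cid}\t{centroid_of[int(cid)]}\n")


def daura_cluster_from_matrix(D: np.ndarray, cutoff: float) -> ClusterResult:
    """Greedy max-neighbour clustering on a precomputed RMSD matrix.

    Neighbourhood is inclusive (``D <= cutoff``); ties on neighbour count go
    to the lowest frame index.  Clusters come back sorted by decreasing
    population, ties by centroid index.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if n == 0:
        raise InputError("empty ensemble")
    if cutoff <= 0:
        raise InputError(f"cutoff must be > 0, got {cutoff}")
    adj = D <= cutoff
    np.fill_diagonal(adj, True)

    alive = np.ones(n, dtype=bool)
    clusters: list[Cluster] = []
    while alive.any():
        counts = (adj & alive[None, :]).sum(axis=1)
        counts[~alive] = -1
        centroid = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.flatnonzero(adj[centroid] & alive)
        clusters.append(Cluster(centroid=centroid, members=tuple(int(m) for m in members)))
        alive[members] = False
    clusters.sort(key=lambda c: (-c.population, c.centroid))
    return ClusterResult(clusters=clusters, cutoff=float(cutoff), n_frames=n)


def daura_cluster(
    ensemble: list[Conformation], cutoff: float, fit: bool = True
) -> ClusterResult:
    """Cluster an ensemble of conformations at an RMSD cut-off (Angstrom)."""
    if not ensemble:
        raise InputError("empty ensemble")
    D = pairwise_rmsd_matrix(ensemble, fit=fit)
    result = daura_cluster_from_matrix(D, cutoff)
    result.centroid_coordinates = [ensemble[c.centroid] for c in result.clusters]
    return result


@dataclass(frozen=True)
class MatchPair:
    """One centroid-pair comparison; clusters identified by population rank (0-based)."""

    cluster_a: int
    cluster_b: int
    rmsd: float
    status: str


@dataclass
class MatchReport:
    pairs: list[MatchPair]
    matched_cutoff: float = MATCH_CUTOFF
    near_matched_cutoff: float = NEAR_MATCH_CUTOFF
    warning: str | None = None

    def counts(self) -> dict[str, int]:
        out = {MATCHED: 0, NEAR_MATCHED: 0, UNMATCHED: 0}
        for p in self.pairs:
            out[p.status] += 1
        return out

    def to_tsv(self, path: str | os.PathLike, header_lines: list[str] | None = None):
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            if self.warning:
                fh.write(f"# warning: {self.warning}\n")
            fh.write("cluster_a\tcluster_b\trmsd_angstrom\tstatus\n")
            for p in self.pairs:
                fh.write(f"{p.cluster_a}\t{p.cluster_b}\t{p.rmsd:.4f}\t{p.status}\n")

    def to_json(self, path: str | os.PathLike | None = None) -> str:
        payload = {
            "matched_cutoff_angstrom": self.matched_cutoff,
            "near_matched_cutoff_angstrom": self.near_matched_cutoff,
            "warning": self.warning,
            "pairs": [
                {
                    "cluster_a": p.cluster_a,
                    "cluster_b": p.cluster_b,
                    "rmsd_angstrom": p.rmsd,
                    "status": p.status,
                }
                for p in self.pairs
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def _classify_pair(rmsd: float, matched: float, near: float) -> str:
    if rmsd <= matched:
        return MATCHED
    if rmsd < near:
        return NEAR_MATCHED
    return UNMATCHED


def cross_cluster_match(
    a: ClusterResult,
    b: ClusterResult,
    top_k: int = 5,
    matched_cutoff: float = MATCH_CUTOFF,
    near_matched_cutoff: float = NEAR_MATCH_CUTOFF,
    fit: bool = True,
) -> MatchReport:
    """Compare centroid structures of the top-k most populated clusters of two runs.

    Every centroid pair among the top-k of each result is compared; when a
    result has fewer than ``top_k`` clusters, the available ones are compared
    and a warning recorded.  Both results must carry centroid coordinates
    (``daura_cluster`` attaches them).
    """
    if top_k < 1:
        raise InputError(f"top_k must be >= 1, got {top_k}")
    if a.centroid_coordinates is None or b.centroid_coordinates is None:
        raise InputError("cluster results lack centroid coordinates")
    ka = min(top_k, len(a.clusters))
    kb = min(top_k, len(b.clusters))
    warning = None
    if ka < top_k or kb < top_k:
        warning = (
            f"requested top {top_k} clusters but only {ka} (A) and {kb} (B) exist"
        )
    pairs = [
        MatchPair(
            cluster_a=i,
            cluster_b=j,
            rmsd=(r := backbone_rmsd(
                a.centroid_coordinates[i], b.centroid_coordinates[j], fit=fit
            )),
            status=_classify_pair(r, matched_cutoff, near_matched_cutoff),
        )
        for i in range(ka)
        for j in range(kb)
    ]
    return MatchReport(
        pairs=pairs,
        matched_cutoff=matched_cutoff,
        near_matched_cutoff=near_matched_cutoff,
        warning=warning,
    )


def extract_backbone(
    traj: Trajectory, atom_names: tuple[str, ...] = DEFAULT_BACKBONE_ATOMS
) -> list[Conformation]:
    """Backbone conformations (one per frame) from the peptide part of a trajectory."""
    _, residues = partition_atoms(traj)
    wanted = set(atom_names)
    idx = [
        i
        for group in residues
        for i in group.atom_indices
        if traj.atoms[i].name in wanted
    ]
    if not idx:
        raise InputError(
            f"no backbone atoms ({'/'.join(atom_names)}) found in the peptide"
        )
    return [
        Conformation(coordinates=frame.coordinates[idx], frame_index=f)
        for f, frame in enumerate(traj.frames)
    ]
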
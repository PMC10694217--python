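"""Single-linkage spatial clustering of group-specific residues.

Far-red-specific residues mapped onto a photosystem I structure tend to form
a few membrane-spanning patches around the chlorophyll-f sites.  Elongated
patches like these are what single linkage preserves and centroid-based
methods split, so the partition here is exactly the set of connected
components of the graph joining C-alpha positions closer than a cutoff
(default 15 A).  Components below ``min_size`` are reported as sparse,
unclustered residues; the rest are labelled c1, c2, ... by decreasing size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist


@dataclass
class ResidueCluster:
    label: str  # c1, c2, ... or "unclustered"
    members: list  # caller-supplied identifiers, input order preserved
    centroid: np.ndarray
    diameter: float


def cluster_residues(
    positions: np.ndarray,
    members: list | None = None,
    cutoff: float = 15.0,
    min_size: int = 5,
) -> list[ResidueCluster]:
    """Single-linkage clusters of C-alpha positions at a distance cutoff.

    Returns proper clusters (size >= min_size) sorted by size descending and
    labelled c1, c2, ..., followed by one "unclustered" group collecting the
    sparse residues, if any.
    """
    X = np.asarray(positions, dtype=float)
    if X.ndim != 2 or X.shape[1] != 3 or X.shape[0] < 1:
        raise ValueError("positions must be a non-empty Nx3 array")
    n = X.shape[0]
    if members is None:
        members = list(range(n))
    if len(members) != n:
        raise ValueError("members length must match positions")
    if n == 1:
        assignment = np.array([1])
    else:
        Z = linkage(pdist(X), method="single")
        # single linkage merged below the cutoff == connected components of
        # the <=cutoff distance graph
        assignment = fcluster(Z, t=cutoff, criterion="distance")
    groups: dict[int, list[int]] = {}
    for i, a in enumerate(assignment):
        groups.setdefault(int(a), []).append(i)
    proper = sorted(
        (idx for idx in groups.values() if len(idx) >= min_size),
        key=lambda idx: (-len(idx), idx[0]),
    )
    sparse = [i for idx in groups.values() if len(idx) < min_size for i in idx]
    out = []
    for k, idx in enumerate(proper, 1):
        pts = X[idx]
        diameter = float(pdist(pts).max()) if len(idx) > 1 else 0.0
        out.append(
            ResidueCluster(
                label=f"c{k}",
                members=[members[i] for i in idx],
                centroid=pts.mean(axis=0),
                diameter=diameter,
            )
        )
    if sparse:
        sparse.sort()
        pts = X[sparse]
        out.append(
            ResidueCluster(
                label="unclustered",
                members=[members[i] for i in sparse],
                centroid=pts.mean(axis=0),
                diameter=float(pdist(pts).max()) if len(sparse) > 1 else 0.0,
            )
        )
    return out


def connected_components_partition(
    positions: np.ndarray, cutoff: float
) -> list[set[int]]:
    """Brute-force partition by BFS on the <=cutoff distance graph.

    Independent of the linkage-based route; used as an oracle to confirm the
    single-linkage partition on every run at small n.
    """
    X = np.asarray(positions, dtype=float)
    n = X.shape[0]
    D = np.linalg.norm(X[:, None] - X[None, :], axis=2)
    unvisited = set(range(n))
    parts = []
    while unvisited:
        start = min(unvisited)
        comp = {start}
        frontier = [start]
        while frontier:
            i = frontier.pop()
            for j in list(unvisited - comp):
                if D[i, j] <= cutoff:
                    comp.add(j)
                    frontier.append(j)
        parts.append(comp)
        unvisited -= comp
    return parts


def write_cluster_tsv(clusters: list[ResidueCluster], path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster\tsize\tdiameter\tmembers\n")
        for c in clusters:
            fh.write(
                f"{c.label}\t{len(c.members)}\t{c.diameter:.2f}\t"
                + ";".join(str(m) for m in c.members)
                + "\n"
            )
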
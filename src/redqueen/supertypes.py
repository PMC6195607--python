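"""Supertype delimitation and lineage tracking in paratope space.

A supertype is a cluster of allele coordinates with similar binding
properties.  On the simulation grid we delimit supertypes by single-linkage
clustering: two alleles belong to the same supertype iff they are connected
by a chain of pairwise Euclidean distances no larger than a threshold
(default 100 grid units, 10% of the grid side).  Lineages of supertypes are
followed through a trajectory by greedy nearest-centroid matching, yielding
persist/move/loss/branch events that summarise how stable supertypes are
over evolutionary time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

Coordinate = tuple[int, int]


@dataclass
class SupertypeAssignment:
    """Partition of alleles into supertypes.

    ``labels`` maps each allele coordinate to an integer supertype label;
    labels are assigned deterministically in order of each cluster's
    lexicographically smallest member.  ``centroids`` are copy-count-weighted
    means of member coordinates and ``sizes`` total copy counts.
    """

    labels: dict[Coordinate, int]
    centroids: dict[int, tuple[float, float]]
    sizes: dict[int, int]

    @property
    def n_supertypes(self) -> int:
        return len(self.centroids)


@dataclass
class LineageEvent:
    """One supertype lineage event between consecutive snapshots."""

    generation: int
    kind: str  # persist | move | loss | branch
    label_old: int | None
    label_new: int | None
    displacement: float


def cluster_supertypes(
    alleles: Mapping[Coordinate, int] | Sequence[Coordinate],
    threshold: float = 100.0,
) -> SupertypeAssignment:
    """Single-linkage clustering of allele coordinates at a distance cutoff.

    Parameters
    ----------
    alleles
        Mapping coordinate -> copy count, or a plain sequence of coordinates
        (each counted once).
    threshold
        Chain distance (grid units) below or at which two alleles share a
        supertype.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if isinstance(alleles, Mapping):
        coords = list(alleles.keys())
        counts = np.array([alleles[c] for c in coords], dtype=float)
    else:
        coords = [tuple(c) for c in alleles]
        counts = np.ones(len(coords))
    if not coords:
        raise ValueError("allele set must be nonempty")

    pts = np.asarray(coords, dtype=float)
    n = len(coords)
    tree = cKDTree(pts)
    pairs = tree.query_pairs(r=threshold, output_type="ndarray")
    if pairs.size:
        data = np.ones(pairs.shape[0])
        adj = csr_matrix((data, (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    else:
        adj = csr_matrix((n, n))
    n_comp, comp = connected_components(adj, directed=False)

    # deterministic labels: order components by their smallest member
    order = {}
    for comp_id in range(n_comp):
        members = [coords[i] for i in np.flatnonzero(comp == comp_id)]
        order[comp_id] = min(members)
    relabel = {
        comp_id: rank
        for rank, comp_id in enumerate(sorted(order, key=order.get))
    }

    labels = {coords[i]: relabel[comp[i]] for i in range(n)}
    centroids: dict[int, tuple[float, float]] = {}
    sizes: dict[int, int] = {}
    for lab in range(n_comp):
        mask = np.array([labels[coords[i]] == lab for i in range(n)])
        w = counts[mask]
        c = pts[mask]
        centroid = (w[:, None] * c).sum(axis=0) / w.sum()
        centroids[lab] = (float(centroid[0]), float(centroid[1]))
        sizes[lab] = int(w.sum())
    return SupertypeAssignment(labels=labels, centroids=centroids, sizes=sizes)


def effective_num_alleles(
    individuals: np.ndarray | Sequence,
) -> float:
    """Inverse Simpson index 1 / sum(p_i^2) over a sample of individuals.

    ``individuals`` is an (n, 2, 2) array (n diploid individuals, two allele
    coordinates each) or any nested sequence reshapeable to it.  Frequencies
    are taken over the 2n allele copies.  Returns 1.0 for a monomorphic
    sample and the number of distinct alleles when frequencies are uniform.
    """
    arr = np.asarray(individuals)
    if arr.size == 0:
        raise ValueError("sample must be nonempty")
    flat = arr.reshape(-1, 2)
    _, counts = np.unique(flat, axis=0, return_counts=True)
    p = counts / counts.sum()
    return float(1.0 / np.sum(p**2))


def _match_snapshots(
    old: SupertypeAssignment | Mapping[int, tuple[float, float]],
    new: SupertypeAssignment | Mapping[int, tuple[float, float]],
    match_radius: float,
    old_sizes: Mapping[int, int] | None = None,
) -> tuple[list[tuple[int, int, float]], list[int], list[int]]:
    """Greedy nearest-centroid matching between two snapshots.

    Candidate (old, new) pairs within ``match_radius`` are taken in order of
    ascending centroid distance, ties broken in favour of the larger old
    cluster, then by label.  Returns (matches, unmatched_old, unmatched_new)
    where ``matches`` may assign several new clusters to one old cluster
    (the extras are branch daughters).
    """
    old_c = old.centroids if isinstance(old, SupertypeAssignment) else dict(old)
    new_c = new.centroids if isinstance(new, SupertypeAssignment) else dict(new)
    sizes = (
        old.sizes if isinstance(old, SupertypeAssignment)
        else (old_sizes or {k: 1 for k in old_c})
    )

    cand = []
    for lo, co in old_c.items():
        for ln, cn in new_c.items():
            d = float(np.hypot(co[0] - cn[0], co[1] - cn[1]))
            if d <= match_radius:
                cand.append((d, -sizes.get(lo, 1), lo, ln))
    cand.sort()

    matches: list[tuple[int, int, float]] = []
    new_taken: set[int] = set()
    for d, _negsize, lo, ln in cand:
        if ln in new_taken:
            continue
        new_taken.add(ln)
        matches.append((lo, ln, d))
    matched_old = {lo for lo, _, _ in matches}
    unmatched_old = [lo for lo in old_c if lo not in matched_old]
    unmatched_new = [ln for ln in new_c if ln not in new_taken]
    return matches, unmatched_old, unmatched_new


def track_supertypes(
    trajectory: Sequence,
    match_radius: float = 150.0,
) -> list[LineageEvent]:
    """Follow supertype lineages through a recorded trajectory.

    For every pair of consecutive snapshots, centroids are matched greedily
    within ``match_radius`` grid units.  The first new cluster matched to an
    old one yields a ``persist`` (displacement 0) or ``move`` event; any
    further new cluster matched to the same old one yields a ``branch``
    event; old clusters with no match yield ``loss`` events.  New clusters
    with no old parent within the radius produce no event.
    """
    if len(trajectory) < 2:
        raise ValueError("trajectory must contain at least two snapshots")
    events: list[LineageEvent] = []
    for prev, cur in zip(trajectory, trajectory[1:]):
        matches, unmatched_old, _ = _match_snapshots(
            _as_assignment(prev), _as_assignment(cur), match_radius
        )
        first_for_old: set[int] = set()
        for lo, ln, d in matches:
            if lo not in first_for_old:
                first_for_old.add(lo)
                kind = "persist" if d == 0.0 else "move"
            else:
                kind = "branch"
            events.append(
                LineageEvent(
                    generation=_gen_of(cur), kind=kind,
                    label_old=lo, label_new=ln, displacement=d,
                )
            )
        for lo in unmatched_old:
            events.append(
                LineageEvent(
                    generation=_gen_of(cur), kind="loss",
                    label_old=lo, label_new=None, displacement=0.0,
                )
            )
    return events


def _as_assignment(snapshot) -> SupertypeAssignment:
    if isinstance(snapshot, SupertypeAssignment):
        return snapshot
    # TrajectoryRecord-like object
    centroids = snapshot.supertype_centroids
    labels = snapshot.supertype_assignment
    sizes: dict[int, int] = {}
    counts = getattr(snapshot, "allele_counts", None)
    for coord, lab in labels.items():
        sizes[lab] = sizes.get(lab, 0) + (counts[coord] if counts else 1)
    return SupertypeAssignment(labels=dict(labels), centroids=dict(centroids),
                               sizes=sizes)


def _gen_of(snapshot) -> int:
    return int(getattr(snapshot, "generation", -1))


def lineage_frame(events: Iterable[LineageEvent]):
    """Events as a tidy DataFrame."""
    import pandas as pd

    return pd.DataFrame(
        [
            (e.generation, e.kind, e.label_old, e.label_new, e.displacement)
            for e in events
        ],
        columns=["generation", "kind", "label_old", "label_new",
                 "displacement"],
    )
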
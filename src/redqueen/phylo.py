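"""Distance phylogenetics for supertype-monophyly testing.

Trans-species polymorphism predicts that alleles of a supertype shared
between species form monophyletic clades.  This module provides the pieces
needed to test that prediction on an aligned set of nucleotide sequences:
Jukes-Cantor distances (pairwise deletion of gap/ambiguous columns),
Saitou-Nei neighbour joining with deterministic tie-breaking, nonparametric
bootstrap support mapped onto bipartitions, an exact monophyly test on the
unrooted tree, and a per-supertype report.

Trees are :class:`skbio.TreeNode` objects (unrooted, represented with a
trifurcating root as NJ produces); bootstrap supports are attached as
``node.support`` percentages and written as internal node labels in Newick
output.
"""

from __future__ import annotations

import logging
from collections import Counter
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger("redqueen")

_VALID = np.frombuffer(b"ACGT", dtype=np.uint8)
JC_MAX_P = 0.75


# ---------------------------------------------------------------------------
# Alignment handling
# ---------------------------------------------------------------------------

def encode_alignment(
    sequences: Mapping[str, str],
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Byte-encode an aligned FASTA-style mapping.

    Returns (ids, (n, L) uint8 matrix, (n, L) bool validity mask where True
    marks an unambiguous A/C/G/T).  Raises on unequal lengths or characters
    outside {A, C, G, T, N, -}.
    """
    if not sequences:
        raise ValueError("alignment is empty")
    ids = list(sequences)
    lengths = {len(sequences[i]) for i in ids}
    if len(lengths) != 1:
        raise ValueError("sequences are not aligned (unequal lengths)")
    mat = np.array(
        [np.frombuffer(sequences[i].upper().encode(), dtype=np.uint8)
         for i in ids]
    )
    allowed = np.frombuffer(b"ACGTN-", dtype=np.uint8)
    if not np.isin(mat, allowed).all():
        bad = sorted({chr(c) for c in np.unique(mat) if c not in allowed})
        raise ValueError(f"invalid alignment characters: {bad}")
    valid = np.isin(mat, _VALID)
    return ids, mat, valid


def read_fasta(path) -> dict[str, str]:
    """Read an aligned FASTA file into an id -> sequence mapping."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n{seq}\n")


# ---------------------------------------------------------------------------
# Jukes-Cantor distances
# ---------------------------------------------------------------------------

def jc_transform(p: float, on_saturation: str = "error",
                 cap: float = 5.0) -> float:
    """Jukes-Cantor correction d = -(3/4) ln(1 - (4/3) p)."""
    if p < 0:
        raise ValueError("proportion of differing sites must be >= 0")
    if p >= JC_MAX_P:
        if on_saturation == "cap":
            logger.warning("saturated p=%.3f capped at distance %.2f", p, cap)
            return cap
        raise ValueError(
            f"p = {p:.4f} >= 0.75: Jukes-Cantor distance undefined"
        )
    return -0.75 * np.log1p(-(4.0 / 3.0) * p)


def jc_distance(seq_i: str, seq_j: str, on_saturation: str = "error",
                cap: float = 5.0) -> float:
    """Jukes-Cantor distance between two aligned sequences.

    The proportion of differing sites is taken over pairwise-complete
    columns only (columns where either sequence has a gap or N are
    excluded).  ``on_saturation`` controls behaviour at p >= 0.75:
    'error' (default) or 'cap' at ``cap``.
    """
    ids, mat, valid = encode_alignment({"i": seq_i, "j": seq_j})
    both = valid[0] & valid[1]
    n = int(both.sum())
    if n == 0:
        raise ValueError("no pairwise-complete columns")
    p = float((mat[0, both] != mat[1, both]).sum() / n)
    return jc_transform(p, on_saturation=on_saturation, cap=cap)


def jc_distance_matrix(
    sequences: Mapping[str, str], on_saturation: str = "error",
    cap: float = 5.0,
) -> tuple[list[str], np.ndarray]:
    """Symmetric Jukes-Cantor distance matrix with pairwise deletion."""
    ids, mat, valid = encode_alignment(sequences)
    n = len(ids)
    D = np.zeros((n, n))
    for i in range(n):
        vi = valid[i]
        diff = (mat[i][None, :] != mat[i + 1:]) & vi[None, :] & valid[i + 1:]
        comp = (vi[None, :] & valid[i + 1:]).sum(axis=1)
        if (comp == 0).any():
            raise ValueError("a sequence pair shares no complete columns")
        p = diff.sum(axis=1) / comp
        d = np.array([jc_transform(x, on_saturation, cap) for x in p])
        D[i, i + 1:] = d
        D[i + 1:, i] = d
    return ids, D


# ---------------------------------------------------------------------------
# Neighbour joining
# ---------------------------------------------------------------------------

def nj_tree(D: np.ndarray, ids: Sequence[str]) -> TreeNode:
    """Saitou-Nei neighbour joining with the Studier-Keppler criterion.

    The pair minimising Q_ij = (r - 2) d_ij - R_i - R_j is joined at each
    step; ties are broken deterministically by the lowest (i, j) index pair.
    Negative branch lengths are clamped to zero.  Returns an unrooted tree
    as a TreeNode with a trifurcating root.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if n < 3:
        raise ValueError("neighbour joining needs at least 3 taxa")
    if D.shape != (n, n) or len(ids) != n:
        raise ValueError("distance matrix and ids disagree in size")
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0.0):
        raise ValueError("distance matrix must be symmetric with zero "
                         "diagonal")

    nodes: list[TreeNode] = [TreeNode(name=str(i)) for i in ids]
    D = D.copy()
    while len(nodes) > 3:
        r = len(nodes)
        R = D.sum(axis=1)
        Q = (r - 2) * D - R[:, None] - R[None, :]
        iu = np.triu_indices(r, k=1)
        # row-major argmin over the upper triangle = lowest (i, j) tie-break
        flat = Q[iu]
        best = int(np.argmin(flat))
        i, j = int(iu[0][best]), int(iu[1][best])

        dij = D[i, j]
        bi = 0.5 * dij + (R[i] - R[j]) / (2.0 * (r - 2))
        bj = dij - bi
        bi, bj = max(bi, 0.0), max(bj, 0.0)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length = bi
        nodes[j].length = bj

        dnew = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [k for k in range(r) if k not in (i, j)]
        Dn = np.zeros((r - 1, r - 1))
        Dn[:-1, :-1] = D[np.ix_(keep, keep)]
        Dn[-1, :-1] = dnew[keep]
        Dn[:-1, -1] = dnew[keep]
        nodes = [nodes[k] for k in keep] + [parent]
        D = Dn

    # final trifurcation from the three-point formulas
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    lengths = (
        0.5 * (d01 + d02 - d12),
        0.5 * (d01 + d12 - d02),
        0.5 * (d02 + d12 - d01),
    )
    root = TreeNode(children=list(nodes))
    for node, ln in zip(nodes, lengths):
        node.length = max(float(ln), 0.0)
    return root


# ---------------------------------------------------------------------------
# Bipartitions, monophyly, bootstrap
# ---------------------------------------------------------------------------

def _leaf_names(tree: TreeNode) -> frozenset:
    return frozenset(leaf.name for leaf in tree.tips())


def bipartitions(tree: TreeNode) -> dict[frozenset, TreeNode]:
    """Internal-edge bipartitions of an unrooted tree.

    Each internal edge is keyed canonically by the side of the split that
    does not contain a fixed reference leaf (the lexicographically smallest
    leaf name).  Trivial splits (single leaves, the full set) are omitted.
    """
    all_leaves = _leaf_names(tree)
    ref = min(all_leaves)
    out: dict[frozenset, TreeNode] = {}
    for node in tree.non_tips(include_self=False):
        clade = frozenset(leaf.name for leaf in node.tips())
        if len(clade) < 2 or len(clade) > len(all_leaves) - 2:
            continue
        key = clade if ref not in clade else all_leaves - clade
        out[key] = node
    return out


def is_monophyletic(tree: TreeNode, tips: Iterable[str]) -> bool:
    """True iff some edge of the unrooted tree separates exactly ``tips``.

    A single tip is trivially monophyletic (its pendant edge separates it).
    """
    tips = frozenset(tips)
    all_leaves = _leaf_names(tree)
    unknown = tips - all_leaves
    if unknown:
        raise ValueError(f"tips not in tree: {sorted(unknown)}")
    if not 1 <= len(tips) < len(all_leaves):
        raise ValueError("tips must be a nonempty proper subset of leaves")
    if len(tips) == 1 or len(tips) == len(all_leaves) - 1:
        return True
    comp = all_leaves - tips
    for clade in _all_clades(tree):
        if clade == tips or clade == comp:
            return True
    return False


def _all_clades(tree: TreeNode) -> Iterable[frozenset]:
    for node in tree.non_tips(include_self=False):
        yield frozenset(leaf.name for leaf in node.tips())


def bootstrap_support(
    sequences: Mapping[str, str],
    n_reps: int = 500,
    rng: np.random.Generator | None = None,
    on_saturation: str = "cap",
) -> TreeNode:
    """NJ tree with bootstrap supports on internal edges.

    Columns are resampled with replacement ``n_reps`` times; a tree is
    rebuilt per replicate and bipartition frequencies (percent of
    replicates) are attached as ``node.support`` to the matching internal
    edges of the full-alignment tree.  Saturated replicate distances are
    capped rather than raised so that resampling noise cannot abort a run.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    ids, mat, valid = encode_alignment(sequences)
    ref_ids, D = jc_distance_matrix(sequences, on_saturation=on_saturation)
    tree = nj_tree(D, ref_ids)
    if np.allclose(D, 0.0):
        logger.warning("degenerate alignment (all sequences identical): "
                       "no bipartition can be supported")
        return tree
    parts = bipartitions(tree)
    if not parts:
        logger.warning("degenerate alignment: tree has no internal "
                       "bipartitions to support")
    counts: Counter = Counter()
    L = mat.shape[1]
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        boot = {
            i: mat[k, cols].tobytes().decode() for k, i in enumerate(ids)
        }
        try:
            bids, bD = jc_distance_matrix(boot, on_saturation=on_saturation)
        except ValueError:
            continue  # replicate with an all-missing pair: uninformative
        btree = nj_tree(bD, bids)
        counts.update(bipartitions(btree).keys())
    for key, node in parts.items():
        node.support = 100.0 * counts[key] / n_reps
    return tree


def write_newick(tree: TreeNode, path) -> None:
    """Write Newick with bootstrap supports as internal node labels."""
    clone = tree.copy()
    for node in clone.non_tips(include_self=False):
        sup = getattr(node, "support", None)
        if sup is not None:
            node.name = f"{sup:g}"
    clone.write(str(path), format="newick")


# ---------------------------------------------------------------------------
# Supertype monophyly report
# ---------------------------------------------------------------------------

def supertype_monophyly_report(
    tree: TreeNode, st_map: Mapping[str, str] | pd.Series
) -> pd.DataFrame:
    """Per-supertype monophyly assessment.

    One row per supertype: number of member alleles in the tree, whether the
    members form a monophyletic group on the unrooted tree, the bootstrap
    support of the separating edge when available, and whether the group is
    a trivial singleton.
    """
    st = (st_map if isinstance(st_map, pd.Series)
          else pd.Series(dict(st_map)))
    leaves = _leaf_names(tree)
    unmapped = sorted(leaves - set(st.index))
    if unmapped:
        raise ValueError(f"leaves without a supertype label: {unmapped[:10]}")
    parts = bipartitions(tree)
    all_leaves = leaves
    ref = min(all_leaves)
    rows = []
    for supertype in sorted(set(st[st.index.isin(leaves)]), key=str):
        members = frozenset(st.index[(st == supertype)
                                     & st.index.isin(leaves)])
        mono = is_monophyletic(tree, members)
        support = np.nan
        if mono and 2 <= len(members) <= len(all_leaves) - 2:
            key = (members if ref not in members
                   else all_leaves - members)
            node = parts.get(key)
            if node is not None:
                support = getattr(node, "support", np.nan)
        rows.append(
            (supertype, len(members), mono, support, len(members) == 1)
        )
    return pd.DataFrame(
        rows,
        columns=["supertype", "n_alleles", "monophyletic", "support",
                 "singleton"],
    ).set_index("supertype")
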
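"""Genetic distances, principal coordinate analysis and neighbor joining.

The default distance for ordination is the codominant genotypic squared
distance for biallelic loci (0 for identical genotypes, 1 when one allele is
shared, 4 for opposite homozygotes), the standard metric for codominant SNP
tables.  Tree building defaults to the p-distance on the IUPAC-concatenated
sequences; Kimura two-parameter is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skbio import DistanceMatrix as SkbioDistanceMatrix
from skbio.tree import TreeNode

from . import popgen
from .io import GenotypeMatrix, IUPACSequenceSet, concatenate_iupac

DISTANCE_METHODS = ("codominant-squared", "p-distance", "K2P")


@dataclass
class GeneticDistanceMatrix:
    """Symmetric pairwise genetic distances with a method tag."""

    ids: list[str]
    data: np.ndarray
    method: str

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.data.shape != (n, n):
            raise ValueError("distance matrix shape inconsistent with ids")
        if not np.allclose(self.data, self.data.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.data) != 0):
            raise ValueError("distance matrix has a nonzero diagonal")
        if np.any(self.data < 0):
            raise ValueError("negative distances")

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_skbio(self) -> SkbioDistanceMatrix:
        return SkbioDistanceMatrix(self.data, ids=self.ids)


def genetic_distance(
    matrix: GenotypeMatrix,
    method: str = "codominant-squared",
    *,
    policy: str = "expected",
) -> GeneticDistanceMatrix:
    """Pairwise genetic distances between samples.

    Missing data: for the codominant metric, per-pair sums are rescaled by
    (total loci / co-typed loci); sequence metrics normalise per co-typed
    site.  A pair with zero co-typed loci is an error.
    """
    if matrix.n_samples < 2:
        raise ValueError("need >= 2 samples")
    if method == "codominant-squared":
        dos = matrix.dosage()
        typed = ~np.isnan(dos)
        X = np.nan_to_num(dos)
        T = typed.astype(float)
        # sum over co-typed loci of (dos_i - dos_j)^2, expanded into matmuls
        sq = X * X
        cross = X @ X.T
        s_i = sq @ T.T
        s_j = T @ sq.T
        ssd = s_i + s_j - 2 * cross
        counts = T @ T.T
        _check_cotyped(counts, matrix.sample_ids)
        D = ssd * (matrix.n_loci / counts)
        np.fill_diagonal(D, 0.0)
        D = np.clip((D + D.T) / 2, 0.0, None)
    elif method in ("p-distance", "K2P"):
        seqs = concatenate_iupac(matrix)
        D = sequence_distance(seqs, method, policy=policy)
    else:
        raise ValueError(f"unknown method {method!r}; choose from {DISTANCE_METHODS}")
    return GeneticDistanceMatrix(ids=list(matrix.sample_ids), data=D, method=method)


def sequence_distance(
    seqs: IUPACSequenceSet, method: str = "p-distance", *, policy: str = "expected"
) -> np.ndarray:
    """Per-site p-distance or K2P distance between IUPAC sequences."""
    diffs, counts = popgen.pairwise_difference_matrix(seqs, policy)
    _check_cotyped(counts, seqs.sample_ids)
    p_tot = diffs / counts
    if method == "p-distance":
        D = p_tot
    elif method == "K2P":
        ts = popgen.pairwise_transition_matrix(seqs)
        P = ts / counts
        Q = p_tot - P
        arg1 = 1.0 - 2.0 * P - Q
        arg2 = 1.0 - 2.0 * Q
        if np.any(arg1 <= 0) or np.any(arg2 <= 0):
            raise ValueError("K2P distance undefined (saturated divergence)")
        D = -0.5 * np.log(arg1 * np.sqrt(arg2))
    else:
        raise ValueError(f"unknown sequence distance {method!r}")
    np.fill_diagonal(D, 0.0)
    return np.clip((D + D.T) / 2, 0.0, None)


def _check_cotyped(counts: np.ndarray, ids: list[str]) -> None:
    bad = np.argwhere(np.triu(counts == 0, k=1))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"samples {ids[i]!r} and {ids[j]!r} share no co-typed loci"
        )


# ---------------------------------------------------------------------------
# principal coordinate analysis


@dataclass
class PCoAResult:
    """Principal coordinates, eigenvalues and per-axis variance percentages.

    ``percent`` is computed over positive eigenvalues only; negative
    eigenvalues (non-Euclidean residue of the distance) are reported apart.
    """

    sample_ids: list[str]
    coordinates: np.ndarray  # (n, n_axes)
    eigenvalues: np.ndarray  # positive eigenvalues, descending
    percent: np.ndarray  # per positive eigenvalue, sums to 100
    negative_eigenvalues: np.ndarray = field(default_factory=lambda: np.empty(0))


def pcoa(d: GeneticDistanceMatrix, n_axes: int = 3) -> PCoAResult:
    """Classical metric multidimensional scaling (Gower centering)."""
    D = d.data
    n = d.n
    B = -0.5 * (D**2)
    row = B.mean(axis=1, keepdims=True)
    col = B.mean(axis=0, keepdims=True)
    B = B - row - col + B.mean()
    evals, evecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(abs(evals[0]), 1.0) * 1e-12 if evals.size else 0.0
    pos = evals > tol
    pos_vals = evals[pos]
    neg_vals = evals[evals < -tol]
    total = pos_vals.sum()
    percent = 100.0 * pos_vals / total if total > 0 else np.zeros(0)
    n_axes = min(n_axes, n)
    coords = np.zeros((n, n_axes))
    for a in range(min(n_axes, pos_vals.size)):
        coords[:, a] = evecs[:, a] * np.sqrt(pos_vals[a])
    return PCoAResult(
        sample_ids=list(d.ids),
        coordinates=coords,
        eigenvalues=pos_vals,
        percent=percent,
        negative_eigenvalues=neg_vals,
    )


# ---------------------------------------------------------------------------
# neighbor joining


@dataclass
class PhyloTree:
    """Unrooted tree (stored with a trifurcating root) plus its total length."""

    tree: TreeNode
    total_length: float

    def newick(self) -> str:
        nwk = str(self.tree).strip()
        return nwk if nwk.endswith(";") else nwk + ";"


def _argmin_q(Q: np.ndarray) -> tuple[int, int]:
    """Lowest-index (i, j), i < j, among the minima of Q's upper triangle."""
    n = Q.shape[0]
    iu = np.triu_indices(n, 1)
    vals = Q[iu]
    m = vals.min()
    pos = np.flatnonzero(vals <= m + 0.0)  # exact ties
    first = pos[0]
    return int(iu[0][first]), int(iu[1][first])


def neighbor_joining(d: GeneticDistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining with nonnegative branch lengths.

    Ties in the Q criterion break toward the lowest index pair; a negative
    branch-length estimate is clamped to zero with the deficit moved to its
    sibling branch, preserving the two-point sum.
    """
    n = d.n
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 samples")
    D = d.data.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=name) for name in d.ids]

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = _argmin_q(Q)
        vi = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        vj = D[i, j] - vi
        vi, vj = _clamp_pair(vi, vj)
        parent = TreeNode()
        nodes[i].length = vi
        nodes[j].length = vj
        parent.extend([nodes[i], nodes[j]])
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [x for x in range(m) if x not in (i, j)]
        D2 = np.empty((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = dnew[keep]
        D2[:-1, -1] = dnew[keep]
        D2[-1, -1] = 0.0
        D = D2
        nodes = [nodes[x] for x in keep] + [parent]

    # final three nodes: three-point formulas around a trifurcating root
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    lens = [
        0.5 * (d01 + d02 - d12),
        0.5 * (d01 + d12 - d02),
        0.5 * (d02 + d12 - d01),
    ]
    root = TreeNode()
    for node, ln in zip(nodes, lens):
        node.length = max(ln, 0.0)
        root.append(node)
    total = sum(
        node.length or 0.0 for node in root.traverse() if node is not root
    )
    return PhyloTree(tree=root, total_length=float(total))


def _clamp_pair(vi: float, vj: float) -> tuple[float, float]:
    if vi < 0:
        vj = max(vj + vi, 0.0)
        vi = 0.0
    elif vj < 0:
        vi = max(vi + vj, 0.0)
        vj = 0.0
    return vi, vj


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Canonical nontrivial leaf bipartitions of an unrooted tree.

    Each internal edge is represented by the smaller side of its split
    (ties broken lexicographically) so topologies compare across rootings.
    """
    leaves = frozenset(l.name for l in tree.tips())
    out: set[frozenset[str]] = set()
    for node in tree.traverse():
        if node.is_tip() or node is tree:
            continue
        side = frozenset(l.name for l in node.tips())
        other = leaves - side
        if len(side) < 2 or len(other) < 2:
            continue
        canon = min(side, other, key=lambda s: (len(s), tuple(sorted(s))))
        out.add(canon)
    return out


def nj_bootstrap(
    matrix: GenotypeMatrix,
    *,
    method: str = "p-distance",
    policy: str = "expected",
    n_boot: int = 100,
    seed: int | None = None,
) -> tuple[PhyloTree, dict[frozenset[str], float]]:
    """NJ tree with bootstrap support from resampling loci with replacement.

    Returns the reference tree (built from all loci) and the fraction of
    bootstrap replicates containing each of its internal bipartitions.
    Support values are also written onto the internal nodes' names.
    """
    ref_dist = genetic_distance(matrix, method, policy=policy)
    ref_tree = neighbor_joining(ref_dist)
    ref_parts = bipartitions(ref_tree.tree)
    counts = {p: 0 for p in ref_parts}
    rng = np.random.default_rng(seed)
    for _ in range(n_boot):
        idx = rng.integers(0, matrix.n_loci, size=matrix.n_loci)
        boot = GenotypeMatrix(
            sample_ids=list(matrix.sample_ids),
            locus_ids=[f"b{i}" for i in range(matrix.n_loci)],
            allele1=matrix.allele1[:, idx].copy(),
            allele2=matrix.allele2[:, idx].copy(),
        )
        parts = bipartitions(neighbor_joining(genetic_distance(boot, method, policy=policy)).tree)
        for p in ref_parts & parts:
            counts[p] += 1
    support = {p: c / n_boot for p, c in counts.items()} if n_boot else {}
    leaves = frozenset(l.name for l in ref_tree.tree.tips())
    for node in ref_tree.tree.traverse():
        if node.is_tip() or node is ref_tree.tree:
            continue
        side = frozenset(l.name for l in node.tips())
        canon = min(side, leaves - side, key=lambda s: (len(s), tuple(sorted(s))))
        if canon in support:
            node.name = f"{support[canon]:.2f}"
    return ref_tree, support
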
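"""Phylogenetic covariance and phylogenetic signal (Blomberg's K, Kmult).

Under Brownian motion on a rooted tree with branch lengths, trait covariance
between species i and j equals the shared root-to-tip branch length, the
(i, j) entry of the phylogenetic covariance matrix C.  Blomberg's K compares
the observed partitioning of trait variance on the tree with the Brownian
expectation (K = 1 under Brownian motion; K -> 0 when relatives are no more
similar than random species).  Kmult is the multivariate generalisation:
sums of squared distances replace univariate sums of squares, so a whole
species x variable matrix (here: PCoA scores of scent distances) yields one
statistic.  Significance comes from a randomisation test that shuffles
species' data across the tips of the phylogeny.

Polytomies are handled natively: C depends only on most-recent-common-
ancestor depths, so unresolved nodes need no arbitrary resolution.
"""

from __future__ import annotations

import copy
import random as _random
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

__all__ = [
    "PhyloCov", "SignalResult", "MatchReport",
    "read_tree", "write_tree", "prune_and_match", "phylo_cov",
    "blomberg_k", "kmult", "permutation_test",
]

#: Relative eigenvalue floor below which C is declared singular
#: (duplicated tips produce identical rows and an exactly zero eigenvalue).
EIG_FLOOR_REL = 1e-10


def read_tree(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True,
               unquoted_underscores=True)


def _normalize_label(label: str) -> str:
    return label.strip().replace(" ", "_").casefold()


@dataclass
class MatchReport:
    """Outcome of matching species names against tree tip labels."""

    matched: dict[str, str]            # species name -> tip label
    unmatched_species: list[str]
    unmatched_tips: list[str]
    genus_fallback: dict[str, str] = field(default_factory=dict)


def prune_and_match(
    tree: dendropy.Tree,
    species: list[str],
    genus_fallback: bool = False,
    seed: int = 0,
) -> tuple[dendropy.Tree, MatchReport]:
    """Restrict a phylogeny to the study species.

    Tip labels and species names are compared after normalising case and
    space/underscore differences.  With ``genus_fallback`` enabled, a species
    absent from the tree is grafted onto a uniformly chosen (seeded) congener
    tip — useful for megatrees that resolve only to genus; off by default.
    """
    if len(tree.leaf_nodes()) == 0:
        raise ValueError("empty tree")
    tip_by_norm: dict[str, str] = {}
    for leaf in tree.leaf_node_iter():
        tip_by_norm[_normalize_label(leaf.taxon.label)] = leaf.taxon.label

    matched: dict[str, str] = {}
    unmatched: list[str] = []
    fallback: dict[str, str] = {}
    for sp in species:
        norm = _normalize_label(sp)
        if norm in tip_by_norm:
            matched[sp] = tip_by_norm[norm]
        else:
            unmatched.append(sp)

    if genus_fallback and unmatched:
        rng = _random.Random(seed)
        taken = set(matched.values())
        still_unmatched = []
        for sp in unmatched:
            genus = _normalize_label(sp).split("_")[0]
            congeners = sorted(
                lbl for key, lbl in tip_by_norm.items()
                if key.split("_")[0] == genus and lbl not in taken
            )
            if congeners:
                pick = rng.choice(congeners)
                fallback[sp] = pick
                matched[sp] = pick
                taken.add(pick)
            else:
                still_unmatched.append(sp)
        unmatched = still_unmatched

    if len(matched) < 3:
        raise ValueError(
            f"only {len(matched)} species matched to the tree; need >= 3"
        )
    # full deep copy (own taxon namespace): pruning and fallback-renaming
    # must never mutate the caller's tree
    pruned = copy.deepcopy(tree)
    keep = set(matched.values())
    pruned.retain_taxa_with_labels(sorted(keep))
    unmatched_tips = sorted(
        set(l.taxon.label for l in tree.leaf_node_iter()) - keep
    )
    # rename fallback tips to the species they stand in for
    if fallback:
        by_tip = {tip: sp for sp, tip in fallback.items()}
        for leaf in pruned.leaf_node_iter():
            if leaf.taxon.label in by_tip:
                leaf.taxon.label = by_tip[leaf.taxon.label]
    report = MatchReport(matched, unmatched, unmatched_tips, fallback)
    return pruned, report


@dataclass
class PhyloCov:
    """Brownian-motion trait covariance implied by a phylogeny.

    ``C[i, j]`` is the depth of the most recent common ancestor of tips i and
    j (their shared root-to-tip branch length); the diagonal holds root-to-tip
    distances.
    """

    labels: list[str]
    C: np.ndarray

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        if self.C.shape != (len(self.labels), len(self.labels)):
            raise ValueError("covariance shape does not match labels")

    def align(self, labels: list[str]) -> "PhyloCov":
        """Reorder to a given label sequence (all labels must be present)."""
        pos = {l: i for i, l in enumerate(self.labels)}
        missing = [l for l in labels if l not in pos]
        if missing:
            raise KeyError(f"labels not in covariance: {missing[:5]}")
        idx = [pos[l] for l in labels]
        return PhyloCov(list(labels), self.C[np.ix_(idx, idx)])


def phylo_cov(tree: dendropy.Tree) -> PhyloCov:
    """Build the phylogenetic covariance matrix from a rooted tree.

    Works on any rooted tree with non-negative branch lengths; polytomies
    need no resolution because only MRCA depths enter the matrix.
    """
    leaves = sorted(tree.leaf_node_iter(), key=lambda l: l.taxon.label)
    labels = [l.taxon.label for l in leaves]
    index = {id(l): i for i, l in enumerate(leaves)}
    n = len(leaves)
    if n < 2:
        raise ValueError("tree must have at least 2 tips")

    # depth of every node measured from the root (root edge ignored)
    depth: dict[int, float] = {id(tree.seed_node): 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        length = node.edge.length if node.edge.length is not None else 0.0
        if length < 0:
            raise ValueError("negative branch length")
        depth[id(node)] = depth[id(node.parent_node)] + length

    C = np.zeros((n, n))
    # postorder: tips under each child subtree of a node share that node's depth
    tipsets: dict[int, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = index[id(node)]
            tipsets[id(node)] = [i]
            C[i, i] = depth[id(node)]
            continue
        children = [tipsets.pop(id(ch)) for ch in node.child_nodes()]
        d = depth[id(node)]
        for a in range(len(children)):
            for b in range(a + 1, len(children)):
                for i in children[a]:
                    C[i, children[b]] = d
                    C[children[b], i] = d
        tipsets[id(node)] = [i for grp in children for i in grp]
    return PhyloCov(labels, C)


# ---------------------------------------------------------------------------
# the statistic
# ---------------------------------------------------------------------------

def _decompose(C: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, float]:
    """Eigendecompose C; return (C_inv, C_inv_sqrt, w = C^-1 1, s = 1'C^-1 1, denom).

    Raises if C is numerically singular (e.g. duplicated tips).
    """
    C = np.asarray(C, dtype=float)
    n = C.shape[0]
    eigval, eigvec = np.linalg.eigh((C + C.T) / 2.0)
    floor = EIG_FLOOR_REL * eigval.max()
    if eigval.min() < floor:
        raise ValueError(
            "phylogenetic covariance is singular (duplicated tips or "
            "zero-depth species?); smallest eigenvalue "
            f"{eigval.min():.3g} vs floor {floor:.3g}"
        )
    inv = (eigvec / eigval) @ eigvec.T
    inv_sqrt = (eigvec / np.sqrt(eigval)) @ eigvec.T
    ones = np.ones(n)
    w = inv @ ones
    s = float(ones @ w)
    denom = (np.trace(C) - n / s) / (n - 1)
    return inv, inv_sqrt, w, s, denom


def blomberg_k(y: np.ndarray, C: PhyloCov | np.ndarray) -> float:
    """Blomberg's K for a single continuous trait.

    K = (SS0 / SS) / [(tr C - N / (1'C^-1 1)) / (N - 1)], with the
    phylogenetic GLS mean a = (1'C^-1 y)/(1'C^-1 1), SS0 = (y-a)'(y-a) and
    SS = (y-a)'C^-1(y-a).  K = 1 is the Brownian-motion expectation.
    """
    y = np.asarray(y, dtype=float)
    Cm = C.C if isinstance(C, PhyloCov) else np.asarray(C, dtype=float)
    if y.shape != (Cm.shape[0],):
        raise ValueError("trait vector length must match covariance dimension")
    inv, _, w, s, denom = _decompose(Cm)
    a = float(w @ y) / s
    r = y - a
    ss0 = float(r @ r)
    if ss0 == 0.0:
        raise ValueError("trait has zero variance; K undefined")
    ss = float(r @ inv @ r)
    return (ss0 / ss) / denom


def kmult(Y: np.ndarray, C: PhyloCov | np.ndarray) -> float:
    """Multivariate phylogenetic signal.

    The GLS grand mean A = (1'C^-1 1)^-1 1'C^-1 Y is removed from every row;
    SS0 is the total squared residual and SS the total squared residual after
    the phylogenetic transformation C^(-1/2) (symmetric square root).  Their
    ratio is scaled by the same tree-only expectation as the univariate K, so
    a single column reduces exactly to Blomberg's K.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.ndim != 2:
        raise ValueError("Y must be a species x variable matrix")
    if Y.shape[1] == 1 and Y.shape[0] == 1:
        raise ValueError("need more than one species")
    Cm = C.C if isinstance(C, PhyloCov) else np.asarray(C, dtype=float)
    if Y.shape[0] != Cm.shape[0]:
        raise ValueError("rows of Y must match covariance dimension")
    _, inv_sqrt, w, s, denom = _decompose(Cm)
    A = (w @ Y) / s
    R = Y - A
    ss0 = float((R ** 2).sum())
    if ss0 == 0.0:
        raise ValueError("data matrix has zero variance; Kmult undefined")
    PR = inv_sqrt @ R
    ss = float((PR ** 2).sum())
    return (ss0 / ss) / denom


@dataclass
class SignalResult:
    """Result of a permutation test for phylogenetic signal."""

    statistic: float
    p_value: float
    n_permutations: int
    null_sample: np.ndarray
    seed: int
    n_axes: int = 1

    def summary(self) -> dict:
        return {
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "n_axes": self.n_axes,
        }


def permutation_test(
    Y: np.ndarray,
    C: PhyloCov | np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
) -> SignalResult:
    """Randomisation test: shuffle species' rows across the tips of the tree.

    Row shuffling preserves the internal correlation structure of Y while
    destroying its association with the phylogeny.  The p-value uses the
    add-one rule p = (1 + #{K_perm >= K_obs}) / (1 + n_perm), so the observed
    arrangement counts as one permutation and p is never 0.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] == 1:
        Y = Y.T
    Cm = C.C if isinstance(C, PhyloCov) else np.asarray(C, dtype=float)
    n, p = Y.shape
    _, inv_sqrt, w, s, denom = _decompose(Cm)

    def _k(Yb: np.ndarray) -> np.ndarray:
        # Yb: (batch, n, p)
        A = np.einsum("n,bnp->bp", w, Yb) / s
        R = Yb - A[:, None, :]
        ss0 = (R ** 2).sum(axis=(1, 2))
        PR = np.einsum("mn,bnp->bmp", inv_sqrt, R)
        ss = (PR ** 2).sum(axis=(1, 2))
        return (ss0 / ss) / denom

    observed = float(_k(Y[None])[0])
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(n) for _ in range(n_perm)])
    null = np.empty(n_perm)
    # batch to bound memory on large n_perm
    step = max(1, int(2e7 // (n * max(p, 1))))
    for lo in range(0, n_perm, step):
        batch = Y[perms[lo:lo + step]]
        null[lo:lo + step] = _k(batch)
    # tolerance so permutation-invariant cases (star tree) count as ties
    n_ge = int((null >= observed * (1 - 1e-9)).sum())
    p_value = (1 + n_ge) / (1 + n_perm)
    return SignalResult(observed, p_value, n_perm, null, seed, n_axes=p)
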
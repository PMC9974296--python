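"""Phylogenetic independent contrasts, Brownian rates of colour evolution,
phylogenetic signal, and divergence-time arithmetic.

Traits are per-tip colour coordinates in a perceptually uniform (JND) space.
Under Brownian motion each axis accrues variance σ²_axis per My along a
branch; squared standardized contrasts estimate that rate. Summing squared
contrasts over the three colour axes per node and averaging across nodes
gives a multivariate rate in units of squared perceptual distance (ΔS²) per
My, from which the expected waiting time for an observed colour divergence
ΔS is T = ΔS²/σ².
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "RateEstimate",
    "SignalResult",
    "read_tree",
    "pic",
    "multivariate_rate",
    "blomberg_K",
    "divergence_time",
]


@dataclass(frozen=True)
class RateEstimate:
    sigma2: float                 # ΔS² My⁻¹
    squared_contrasts: np.ndarray  # per internal node, summed over axes
    n_nodes: int


@dataclass(frozen=True)
class SignalResult:
    K: float
    p_value: float
    n_permutations: int
    seed: int | None


def read_tree(source: str, schema: str = "newick") -> dendropy.Tree:
    """Read and validate a rooted, bifurcating tree with positive branch
    lengths (My). ``source`` is a path or a newick string."""
    if schema == "newick" and source.lstrip().startswith("("):
        tree = dendropy.Tree.get(data=source, schema=schema)
    else:
        tree = dendropy.Tree.get(path=source, schema=schema)
    validate_tree(tree)
    return tree


def validate_tree(tree: dendropy.Tree) -> None:
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise ValueError("tip labels must be unique")
    for node in tree.preorder_node_iter():
        children = node.child_nodes()
        if children and len(children) != 2:
            raise ValueError("tree must be bifurcating (polytomy found)")
        if node.parent_node is not None and (
            node.edge.length is None or node.edge.length <= 0
        ):
            raise ValueError("all branch lengths must be positive")


def _tip_values(tree: dendropy.Tree, traits: pd.Series | dict) -> dict:
    vals = dict(traits)
    out = {}
    for lf in tree.leaf_node_iter():
        lab = lf.taxon.label
        if lab not in vals:
            raise ValueError(f"missing trait value for tip {lab!r}")
        out[lf] = float(vals[lab])
    return out


def pic(tree: dendropy.Tree, traits) -> np.ndarray:
    """Standardized phylogenetic independent contrasts, one per internal
    node, by the pruning algorithm: contrast = (x_L − x_R)/√(b_L + b_R) with
    ancestral branch lengths inflated by b_L·b_R/(b_L + b_R)."""
    validate_tree(tree)
    x = _tip_values(tree, traits)
    blen: dict = {}
    contrasts = []
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            blen[node] = float(node.edge.length or 0.0)
            continue
        left, right = node.child_nodes()
        bl, br = blen[left], blen[right]
        contrasts.append((x[left] - x[right]) / np.sqrt(bl + br))
        x[node] = (x[left] / bl + x[right] / br) / (1.0 / bl + 1.0 / br)
        b = float(node.edge.length or 0.0)
        blen[node] = b + bl * br / (bl + br)
    return np.asarray(contrasts)


def multivariate_rate(tree: dendropy.Tree, tip_traits: pd.DataFrame) -> RateEstimate:
    """Multivariate Brownian rate: per internal node the squared contrast
    length summed over trait axes; σ² is the mean across the n−1 nodes.

    ``tip_traits`` is indexed by tip label with one column per axis.
    """
    sq = None
    for col in tip_traits.columns:
        c = pic(tree, tip_traits[col])
        sq = c**2 if sq is None else sq + c**2
    return RateEstimate(
        sigma2=float(sq.mean()), squared_contrasts=sq, n_nodes=sq.size
    )


def _vcv(tree: dendropy.Tree, order: list[str]) -> np.ndarray:
    """Tree covariance: shared root-to-MRCA path length between tip pairs."""
    depth: dict = {}
    for node in tree.preorder_node_iter():
        d = depth.get(node.parent_node, 0.0)
        depth[node] = d + float(node.edge.length or 0.0)
    leaves = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    # collect tip sets below each node
    below: dict = {}
    n = len(order)
    C = np.zeros((n, n))
    pos = {lab: i for i, lab in enumerate(order)}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = [node.taxon.label]
            C[pos[node.taxon.label], pos[node.taxon.label]] = depth[node]
            continue
        kids = [below[c] for c in node.child_nodes()]
        for a in range(len(kids)):
            for b in range(a + 1, len(kids)):
                for la in kids[a]:
                    for lb in kids[b]:
                        C[pos[la], pos[lb]] = C[pos[lb], pos[la]] = depth[node]
        below[node] = [t for k in kids for t in k]
    return C


def _K_stat(Y: np.ndarray, Ci: np.ndarray, C: np.ndarray) -> float:
    """Multivariate Blomberg K for centred data rows against tree covariance."""
    n = Y.shape[0]
    ones = np.ones(n)
    w = Ci @ ones
    ahat = (w @ Y) / (ones @ w)  # phylogenetically weighted mean per axis
    R = Y - ahat
    mse0 = float(np.sum(R * R))
    mse = float(np.sum(R * (Ci @ R)))
    if mse0 == 0 or mse == 0:
        raise ValueError("K undefined for zero-variance traits")
    expected = (np.trace(C) - n / np.sum(Ci)) / (n - 1)
    return (mse0 / mse) / expected


def blomberg_K(
    tree: dendropy.Tree,
    tip_traits: pd.DataFrame,
    n_perm: int = 999,
    seed: int | None = None,
) -> SignalResult:
    """Multivariate phylogenetic signal K with a tip-permutation test.

    K compares the observed dispersion of tip values around the phylogenetic
    mean with its tree-covariance-corrected counterpart, scaled by the
    Brownian-motion expectation; K ≈ 1 under Brownian motion and falls
    toward 0 when trait values are decoupled from the tree. The p-value is
    the proportion of tip-permuted K values at least as large as the
    observed one, with the observed statistic included in the null set.
    """
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    validate_tree(tree)
    order = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    Y = tip_traits.loc[order].to_numpy(dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    C = _vcv(tree, order)
    Ci = np.linalg.inv(C)
    k_obs = _K_stat(Y, Ci, C)
    rng = np.random.default_rng(seed)
    n = Y.shape[0]
    hits = 1  # the observed value belongs to the null set
    for _ in range(n_perm):
        k_perm = _K_stat(Y[rng.permutation(n)], Ci, C)
        if k_perm >= k_obs:
            hits += 1
    return SignalResult(
        K=float(k_obs),
        p_value=hits / (n_perm + 1),
        n_permutations=n_perm,
        seed=seed,
    )


def divergence_time(delta_s: float, sigma2: float) -> float:
    """Expected time (My) to accrue a colour divergence of ΔS JND under
    Brownian motion at rate σ² (ΔS² My⁻¹): T = ΔS²/σ²."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    if delta_s < 0:
        raise ValueError("delta_s must be non-negative")
    return delta_s**2 / sigma2
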
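"""Phylogeny handling: Newick I/O, cophenetic distances, Blomberg's K with
a tip-permutation test, and pure-birth tree / Brownian trait simulation.

K compares the observed ratio of the ordinary to the phylogenetically
corrected mean squared error of tip values with its Brownian-motion
expectation on the same tree; K near 1 is the Brownian expectation,
K > 1 stronger-than-Brownian signal, K < 1 weaker (overdispersed) signal.
(Note: the conventional reading, under which K around 1 indicates trait
evolution consistent with Brownian motion on the tree, is used throughout.)
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd


def read_newick(path, strict: bool = True) -> dendropy.Tree:
    """Read a rooted Newick tree; in strict mode every edge needs a length."""
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    if strict:
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue
            if edge.length is None:
                raise ValueError(
                    f"missing branch length above node "
                    f"{edge.head_node.taxon.label if edge.head_node.taxon else '<internal>'}"
                )
            if edge.length < 0:
                raise ValueError("negative branch length")
    labels = [t.label for t in tree.taxon_namespace]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate tip labels")
    return tree


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def tip_labels(tree: dendropy.Tree) -> list:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def cophenetic_distances(tree: dendropy.Tree) -> pd.DataFrame:
    """Patristic (path-length) distance between every pair of tips."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = [leaf.taxon for leaf in tree.leaf_node_iter()]
    labels = [t.label for t in taxa]
    n = len(taxa)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return pd.DataFrame(D, index=labels, columns=labels)


def bm_covariance(tree: dendropy.Tree) -> pd.DataFrame:
    """Shared root-to-tip path length C_ij (the Brownian covariance, sigma2=1)."""
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    depths = {leaf.taxon.label: leaf.root_distance for leaf in tree.leaf_node_iter()}
    D = cophenetic_distances(tree)
    labels = list(D.index)
    t = np.array([depths[l] for l in labels])
    C = (t[:, None] + t[None, :] - D.to_numpy()) / 2.0
    np.fill_diagonal(C, t)
    return pd.DataFrame(C, index=labels, columns=labels)


# ---------------------------------------------------------------- Blomberg K

def _k_from_parts(y: np.ndarray, Linv: np.ndarray, ones_Cinv: np.ndarray,
                  denom_expected: float) -> float:
    # MSE is computed in whitened form ||L^-1 resid||^2 (L the Cholesky
    # factor of C) so it stays nonnegative on near-singular trees
    a_hat = float(ones_Cinv @ y) / float(ones_Cinv.sum())
    resid = y - a_hat
    mse0 = float(resid @ resid)
    w = Linv @ resid
    mse = float(w @ w)
    if mse <= 0:
        raise ValueError("degenerate phylogenetic MSE")
    return (mse0 / mse) / denom_expected


def _k_machinery(Cm: np.ndarray):
    from scipy import linalg as sla
    n = Cm.shape[0]
    # tiny jitter guards Cholesky on trees with near-duplicate tips
    jitter = 1e-10 * np.trace(Cm) / n
    L = sla.cholesky(Cm + jitter * np.eye(n), lower=True)
    Linv = sla.solve_triangular(L, np.eye(n), lower=True)
    Cinv = Linv.T @ Linv
    ones_Cinv = Cinv.sum(axis=0)
    denom = (np.trace(Cm) - n / float(ones_Cinv.sum())) / (n - 1)
    return Linv, ones_Cinv, denom


def blomberg_k(tree: dendropy.Tree, traits: pd.Series) -> float:
    """Blomberg's K for one continuous trait on the tree.

    K = (MSE0/MSE) / [(tr(C) - n / sum(C^-1)) / (n - 1)], where MSE0 uses the
    phylogenetically estimated mean and MSE the Brownian covariance C implied
    by the tree. Scale- and location-invariant in the trait.
    """
    C = bm_covariance(tree)
    labels = list(C.index)
    missing = [l for l in labels if l not in traits.index]
    if missing:
        raise ValueError(f"trait values missing for tips: {missing[:5]}")
    y = traits.loc[labels].to_numpy(float)
    if len(y) < 4:
        raise ValueError("Blomberg's K needs at least 4 tips")
    if np.var(y) == 0:
        raise ValueError("constant trait: K undefined")
    try:
        Linv, ones_Cinv, denom = _k_machinery(C.to_numpy())
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular phylogenetic covariance matrix") from exc
    return _k_from_parts(y, Linv, ones_Cinv, denom)


def k_permutation_test(tree: dendropy.Tree, traits: pd.Series,
                       n_perm: int = 999, seed=None):
    """Tip-shuffle test of phylogenetic signal.

    Returns (K_observed, p) with p = (#{K_perm >= K_obs} + 1) / (n_perm + 1).
    """
    if n_perm <= 0:
        raise ValueError("permutations required (n_perm >= 1)")
    C = bm_covariance(tree)
    labels = list(C.index)
    y = traits.loc[labels].to_numpy(float)
    if np.var(y) == 0:
        raise ValueError("constant trait: K undefined")
    Linv, ones_Cinv, denom = _k_machinery(C.to_numpy())
    k_obs = _k_from_parts(y, Linv, ones_Cinv, denom)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        k_b = _k_from_parts(rng.permutation(y), Linv, ones_Cinv, denom)
        if k_b >= k_obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return k_obs, p


# ---------------------------------------------------------------- simulation

@dataclass
class TreeTraitSim:
    tree: dendropy.Tree
    traits: pd.Series  # one BM trait per tip


def simulate_pure_birth(n_tips: int, birth_rate: float = 1.0, seed=None) -> dendropy.Tree:
    """Yule (pure-birth) tree with ``n_tips`` extant tips."""
    if n_tips < 2:
        raise ValueError("need at least two tips")
    from dendropy.simulate import treesim
    rng = random.Random(None if seed is None else int(seed))
    tree = treesim.birth_death_tree(
        birth_rate=birth_rate, death_rate=0.0,
        num_extant_tips=n_tips, rng=rng,
    )
    # the simulator stops at the n-th speciation, leaving zero-length
    # terminal branches; run the clock on to the next (unrealized) birth
    extra = rng.expovariate(birth_rate * n_tips)
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
        leaf.taxon.label = f"sp{i + 1:03d}"
    return tree


def simulate_bm(tree: dendropy.Tree, sigma2: float = 1.0, seed=None,
                root_value: float = 0.0) -> pd.Series:
    """Brownian trait along the branches: each edge adds N(0, sigma2 * length)."""
    rng = np.random.default_rng(seed)
    values = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            node._bm_value = root_value
        else:
            ln = node.edge.length or 0.0
            node._bm_value = node.parent_node._bm_value + rng.normal(
                0.0, np.sqrt(sigma2 * ln))
        if node.is_leaf():
            values[node.taxon.label] = node._bm_value
    return pd.Series(values, name="bm_trait")


def simulate_tree_and_traits(n_tips: int, birth_rate: float = 1.0,
                             sigma2: float = 1.0, seed=None) -> TreeTraitSim:
    """Pure-birth tree plus one Brownian trait; fully determined by ``seed``."""
    tree = simulate_pure_birth(n_tips, birth_rate, seed=seed)
    traits = simulate_bm(tree, sigma2=sigma2,
                         seed=None if seed is None else seed + 1)
    return TreeTraitSim(tree=tree, traits=traits)
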
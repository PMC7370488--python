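"""Synthetic data generation: random trees, additive/noisy distance
matrices, and sequences simulated along a tree under JC or HKY.

Everything downstream of this module (distance estimation, missingness,
imputation, tree building, RF scoring) can be exercised end-to-end from a
seed alone — no external data needed.  All generators are pure functions
of their configuration and seed.

The default two-gene alignment mirrors the common mitochondrial design of
two concatenated protein-coding genes (e.g. COI + CytB), which is what the
indirect missingness mechanism (:func:`~distimpute.missingness.remove_gene_blocks`)
operates on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import dendropy
import numpy as np
from scipy.linalg import expm

from .distances import Alignment
from .matrix import MaskedDistanceMatrix
from .missingness import GenePartition
from .trees import PhyloTree, additive_matrix

__all__ = ["SimConfig", "random_tree", "perturbed_matrix", "simulate_alignment", "hky_rate_matrix"]


@dataclass(frozen=True)
class SimConfig:
    """Simulation settings.

    Branch lengths are i.i.d. Uniform[blen_lo, blen_hi] substitutions/site
    (default [0.05, 0.5], a realistic range for moderately diverged
    mitochondrial genes).  ``gene_lengths`` gives the per-gene site counts
    of the concatenated alignment; ``kappa`` is the HKY
    transition/transversion rate ratio (kappa=1 with uniform frequencies
    is Jukes-Cantor).  ``sigma`` is the relative noise level used by
    :func:`perturbed_matrix`.
    """

    n_taxa: int = 20
    blen_lo: float = 0.05
    blen_hi: float = 0.5
    gene_lengths: tuple[int, ...] = (500, 500)
    kappa: float = 2.0
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")
        if not 0 < self.blen_lo <= self.blen_hi:
            raise ValueError("need 0 < blen_lo <= blen_hi")
        if any(g < 1 for g in self.gene_lengths):
            raise ValueError("gene lengths must be >= 1")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        freqs = np.asarray(self.base_freqs, float)
        if freqs.shape != (4,) or np.any(freqs <= 0) or abs(freqs.sum() - 1) > 1e-9:
            raise ValueError("base_freqs must be four positive values summing to 1")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def random_tree(cfg: SimConfig) -> PhyloTree:
    """Uniformly random unrooted binary topology with i.i.d. branch lengths.

    Built by sequential random attachment: starting from the 3-leaf star,
    each further leaf subdivides a uniformly chosen edge — this yields the
    uniform distribution over unrooted binary topologies.  Branch lengths
    are drawn Uniform[blen_lo, blen_hi] in a fixed traversal order, so the
    tree is a deterministic function of the config.
    """
    n = cfg.n_taxa
    rng = np.random.default_rng(cfg.seed)
    labels = [f"t{i + 1}" for i in range(n)]
    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node

    leaves = [dendropy.Node(taxon=taxa.get_taxon(lab)) for lab in labels]
    if n == 2:
        for lf in leaves:
            root.add_child(lf)
    else:
        for lf in leaves[:3]:
            root.add_child(lf)
        # edges identified by their child node
        edges = list(leaves[:3])
        for lf in leaves[3:]:
            child = edges[int(rng.integers(len(edges)))]
            parent = child.parent_node
            mid = dendropy.Node()
            parent.remove_child(child)
            parent.add_child(mid)
            mid.add_child(child)
            mid.add_child(lf)
            edges.extend([mid, lf])
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = float(rng.uniform(cfg.blen_lo, cfg.blen_hi))
    tree.is_rooted = False
    return tree


def perturbed_matrix(tree: PhyloTree, sigma: float, seed: int) -> MaskedDistanceMatrix:
    """Additive path-length matrix with multiplicative noise.

    Each unordered pair's distance is multiplied by (1 + eps) with
    eps ~ Normal(0, sigma^2), redrawn if the factor would be non-positive
    so entries stay positive.  ``sigma=0`` returns the exact additive
    matrix.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    m = additive_matrix(tree)
    if sigma == 0:
        return m
    rng = np.random.default_rng(seed)
    values = m.values.copy()
    n = m.n_taxa
    for i in range(1, n):
        for j in range(i):
            factor = 1.0 + rng.normal(0.0, sigma)
            while factor <= 0.0:
                factor = 1.0 + rng.normal(0.0, sigma)
            values[i, j] = values[j, i] = m.values[i, j] * factor
    return MaskedDistanceMatrix(m.labels, values)


def hky_rate_matrix(
    kappa: float, base_freqs: tuple[float, float, float, float]
) -> np.ndarray:
    """HKY85 instantaneous rate matrix (order A, C, G, T), scaled so the
    expected substitution rate at stationarity is 1 — branch lengths are
    then in expected substitutions per site."""
    pi = np.asarray(base_freqs, float)
    q = np.zeros((4, 4))
    transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            rate = pi[j] * (kappa if (i, j) in transitions else 1.0)
            q[i, j] = rate
    np.fill_diagonal(q, -q.sum(axis=1))
    mu = -float(pi @ q.diagonal())
    return q / mu


def _evolve(
    parent_states: np.ndarray, p: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Sample child states site-by-site from transition matrix rows."""
    u = rng.random(parent_states.shape[0])
    cum = np.cumsum(p, axis=1)
    return (u[:, None] > cum[parent_states]).sum(axis=1)


def simulate_alignment(
    tree: PhyloTree, cfg: SimConfig
) -> tuple[Alignment, GenePartition]:
    """Simulate sequences along the tree under HKY and return the
    concatenated multi-gene alignment plus its gene partition.

    Sites evolve independently: root states are drawn from the stationary
    frequencies and each branch applies the transition matrix
    P(t) = expm(Q t).  Genes share the tree and model; since sites are
    i.i.d., the gene partition simply labels contiguous blocks.
    """
    rng = np.random.default_rng(cfg.seed)
    q = hky_rate_matrix(cfg.kappa, cfg.base_freqs)
    pi = np.asarray(cfg.base_freqs, float)
    total_len = int(sum(cfg.gene_lengths))

    # cache P(t) per distinct branch length
    p_cache: dict[float, np.ndarray] = {}

    def p_matrix(t: float) -> np.ndarray:
        if t not in p_cache:
            p_cache[t] = expm(q * t)
        return p_cache[t]

    states: dict[int, np.ndarray] = {}
    root = tree.seed_node
    states[id(root)] = (
        rng.random(total_len)[:, None] > np.cumsum(pi)[None, :]
    ).sum(axis=1)
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        t = node.edge.length if node.edge.length is not None else 0.0
        if t == 0.0:
            child = states[id(node.parent_node)].copy()
        else:
            child = _evolve(states[id(node.parent_node)], p_matrix(t), rng)
        states[id(node)] = child

    alpha = np.array(list("ACGT"))
    labels, seqs = [], []
    for lf in tree.leaf_node_iter():
        labels.append(lf.taxon.label)
        seqs.append("".join(alpha[states[id(lf)]]))

    blocks = []
    pos = 1
    for gi, glen in enumerate(cfg.gene_lengths):
        blocks.append((f"gene{gi + 1}", pos, pos + glen - 1))
        pos += glen
    return Alignment(tuple(labels), tuple(seqs)), GenePartition(tuple(blocks))
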